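"""Tensor-train cross interpolation and magnitude maximization.

A d-dimensional array (tensor) ``A`` with mode sizes ``n_1 .. n_d`` is
represented in tensor-train (TT) form as a chain of three-way cores
``G_1 .. G_d``::

    A[i_1, .., i_d] = G_1[:, i_1, :] @ G_2[:, i_2, :] @ .. @ G_d[:, i_d, :]

with core ``G_k`` shaped ``(r_{k-1}, n_k, r_k)`` and boundary ranks
``r_0 = r_d = 1``.  Storage and evaluation cost grow linearly in ``d``,
which is what makes TT usable where the dense tensor is astronomically
large.

The tensor of interest is never materialised: it is an *oracle* — a
callable on integer multi-indices (:class:`ImplicitTensor`).  TT-cross
builds an interpolating TT from a small, adaptively chosen set of
entries, steering the selection with maximal-volume (``maxvol``)
submatrices of the unfolding matrices.  Because cross interpolation
gravitates toward large-magnitude entries, it doubles as a global
optimizer: :func:`tt_magnitude_maximize` iterates cross interpolation,
harvests the large-magnitude interpolation points, optionally refines
them through a caller-supplied local-search callback, and re-injects the
best points into the interpolation sets.

This module is agnostic of molecules; the docking engine supplies the
energy-based oracle and the refinement callback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "TensorTrain",
    "ImplicitTensor",
    "CrossState",
    "DegenerateMatrixError",
    "tt_element",
    "maxvol",
    "tt_cross_interpolate",
    "tt_magnitude_maximize",
]


class DegenerateMatrixError(ValueError):
    """Raised when maxvol is given a rank-deficient matrix."""


# ---------------------------------------------------------------------------
# TT representation
# ---------------------------------------------------------------------------


@dataclass
class TensorTrain:
    """Chain of three-way cores representing a d-dimensional array.

    Parameters
    ----------
    cores
        Sequence of ``d`` arrays, core ``k`` shaped ``(r_{k-1}, n_k, r_k)``
        with ``r_0 = r_d = 1`` and consistent chaining.
    """

    cores: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.cores:
            raise ValueError("TensorTrain needs at least one core")
        self.cores = [np.asarray(c, dtype=float) for c in self.cores]
        for k, c in enumerate(self.cores):
            if c.ndim != 3:
                raise ValueError(f"core {k} is not three-way (shape {c.shape})")
        if self.cores[0].shape[0] != 1 or self.cores[-1].shape[2] != 1:
            raise ValueError("boundary TT-ranks must equal 1")
        for k in range(len(self.cores) - 1):
            if self.cores[k].shape[2] != self.cores[k + 1].shape[0]:
                raise ValueError(
                    f"rank mismatch between cores {k} and {k + 1}: "
                    f"{self.cores[k].shape} vs {self.cores[k + 1].shape}"
                )

    @property
    def d(self) -> int:
        return len(self.cores)

    @property
    def mode_sizes(self) -> tuple[int, ...]:
        return tuple(c.shape[1] for c in self.cores)

    @property
    def ranks(self) -> tuple[int, ...]:
        return (1,) + tuple(c.shape[2] for c in self.cores)

    def __getitem__(self, idx: Sequence[int]) -> float:
        return tt_element(self, idx)

    def full(self) -> np.ndarray:
        """Densify (tests and tiny tensors only)."""
        res = self.cores[0]  # (1, n_1, r_1)
        for c in self.cores[1:]:
            res = np.tensordot(res, c, axes=(-1, 0))
        return res.reshape(self.mode_sizes)


def tt_element(tt: TensorTrain, idx: Sequence[int]) -> float:
    """Evaluate one tensor entry by the chained core product."""
    idx = tuple(int(i) for i in idx)
    if len(idx) != tt.d:
        raise IndexError(f"index length {len(idx)} != tensor order {tt.d}")
    for k, (i, n) in enumerate(zip(idx, tt.mode_sizes)):
        if not 0 <= i < n:
            raise IndexError(f"index {i} out of range for mode {k} (size {n})")
    v = tt.cores[0][:, idx[0], :]
    for k in range(1, tt.d):
        v = v @ tt.cores[k][:, idx[k], :]
    return float(v[0, 0])


# ---------------------------------------------------------------------------
# Implicit tensor (the oracle)
# ---------------------------------------------------------------------------


class ImplicitTensor:
    """A tensor defined by a callable on 0-based integer multi-indices.

    Every evaluation increments :attr:`evaluation_counter`; when
    :attr:`record_log` is set, each ``(multi-index, value)`` pair is
    appended to :attr:`log`.
    """

    def __init__(
        self,
        evaluator: Callable[[tuple[int, ...]], float],
        mode_sizes: Sequence[int],
        record_log: bool = False,
    ) -> None:
        self.evaluator = evaluator
        self.mode_sizes = tuple(int(n) for n in mode_sizes)
        if any(n < 1 for n in self.mode_sizes):
            raise ValueError("mode sizes must be positive")
        self.evaluation_counter = 0
        self.record_log = record_log
        self.log: list[tuple[tuple[int, ...], float]] = []

    @property
    def d(self) -> int:
        return len(self.mode_sizes)

    def __call__(self, idx: Sequence[int]) -> float:
        idx = tuple(int(i) for i in idx)
        for k, (i, n) in enumerate(zip(idx, self.mode_sizes)):
            if not 0 <= i < n:
                raise IndexError(f"index {i} out of range for mode {k} (size {n})")
        try:
            val = float(self.evaluator(idx))
        except Exception as exc:  # attach the offending multi-index
            exc.args = exc.args + (f"while evaluating tensor entry {idx}",)
            raise
        self.evaluation_counter += 1
        if self.record_log:
            self.log.append((idx, val))
        return val

    def eval_many(self, indices: Sequence[tuple[int, ...]]) -> np.ndarray:
        return np.array([self(ix) for ix in indices], dtype=float)


# ---------------------------------------------------------------------------
# maxvol
# ---------------------------------------------------------------------------


def maxvol(
    matrix: np.ndarray, tol: float = 1e-2, max_sweeps: int = 100
) -> np.ndarray:
    """Select a dominant r x r submatrix of a tall n x r matrix.

    Returns row indices ``rows`` such that every entry of
    ``matrix @ inv(matrix[rows])`` has magnitude <= 1 + tol (dominance):
    no single row swap can then increase |det| by more than that factor.

    Greedy row-swap sweeps (each swap strictly increases the volume, so
    the loop terminates at a local volume maximum) run from several
    deterministic starting selections — column-pivoted QR, LU pivot
    rows, and a few restarts seeded from the matrix content — and the
    largest-volume converged selection is returned.  Multi-start local
    search is cheap at these block sizes and reliably escapes the rare
    single-swap-stable selections whose volume is noticeably
    sub-maximal.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2:
        raise ValueError("maxvol expects a 2-D array")
    n, r = a.shape
    if n < r:
        raise ValueError(f"matrix must be tall: shape {a.shape}")
    if np.linalg.matrix_rank(a) < r:
        raise DegenerateMatrixError(
            f"matrix of shape {a.shape} is rank-deficient; maxvol undefined"
        )
    if n == r:
        return np.arange(r)

    inits: list[np.ndarray] = []
    _, _, piv = scipy.linalg.qr(a.T, pivoting=True)
    inits.append(np.array(piv[:r], dtype=int))
    p, _, _ = scipy.linalg.lu(a, p_indices=True)
    inits.append(np.array(p[:r], dtype=int))
    restart_rng = np.random.default_rng(
        (int(np.abs(a).sum() * 1e6) + n * 131 + r) % (2 ** 31))
    for _ in range(4):
        inits.append(restart_rng.choice(n, size=r, replace=False))

    best_rows: np.ndarray | None = None
    best_vol = -np.inf
    any_converged = False
    for init in inits:
        rows, converged = _maxvol_sweeps(a, init, max_sweeps)
        if rows is None:
            continue
        sign, logdet = np.linalg.slogdet(a[rows])
        if sign != 0 and logdet > best_vol:
            best_vol, best_rows = logdet, rows
            any_converged = any_converged or converged
    if best_rows is None:  # cannot happen for full-rank input
        raise DegenerateMatrixError("no nonsingular row selection found")
    if not any_converged:
        warnings.warn(
            "maxvol did not converge to the dominance tolerance; "
            "returning best row set found",
            RuntimeWarning,
            stacklevel=2,
        )
    return best_rows


def _maxvol_sweeps(
    a: np.ndarray, rows: np.ndarray, max_sweeps: int
) -> tuple[np.ndarray | None, bool]:
    """Row-swap local search; returns (rows, converged) or (None, False)
    when the starting selection is singular."""
    rows = np.array(rows, dtype=int)
    for _ in range(max_sweeps):
        try:
            b = np.linalg.solve(a[rows].T, a.T).T  # = a @ inv(a[rows])
        except np.linalg.LinAlgError:
            return None, False
        if not np.all(np.isfinite(b)):
            return None, False
        i, j = np.unravel_index(np.argmax(np.abs(b)), b.shape)
        if abs(b[i, j]) <= 1.0 + 1e-9:  # strict local volume maximum
            return rows, True
        rows[j] = i
    return rows, False


# ---------------------------------------------------------------------------
# Cross interpolation
# ---------------------------------------------------------------------------


@dataclass
class CrossState:
    """Interpolation point sets of the unfolding matrices, plus bookkeeping.

    For each boundary ``k`` between dimensions ``k`` and ``k+1``
    (``k = 0 .. d-2``), ``row_sets[k]`` holds prefix multi-indices of
    length ``k + 1`` and ``col_sets[k]`` holds suffix multi-indices of
    length ``d - k - 1``.  ``best_points`` keeps the largest-magnitude
    entries seen so far, best first.
    """

    row_sets: list[list[tuple[int, ...]]]
    col_sets: list[list[tuple[int, ...]]]
    best_points: list[tuple[tuple[int, ...], float]] = field(default_factory=list)
    iteration: int = 0

    @classmethod
    def random_init(
        cls, mode_sizes: Sequence[int], size: int, rng: np.random.Generator
    ) -> "CrossState":
        """Seed every interpolation set with ``size`` random in-range points."""
        d = len(mode_sizes)
        full = [
            tuple(int(rng.integers(0, n)) for n in mode_sizes) for _ in range(size)
        ]
        rows = [[x[: k + 1] for x in full] for k in range(d - 1)]
        cols = [[x[k + 1:] for x in full] for k in range(d - 1)]
        return cls(row_sets=[_dedup(s) for s in rows],
                   col_sets=[_dedup(s) for s in cols])

    def validate(self, mode_sizes: Sequence[int]) -> None:
        d = len(mode_sizes)
        if len(self.row_sets) != d - 1 or len(self.col_sets) != d - 1:
            raise ValueError("state has wrong number of interpolation sets")
        for k in range(d - 1):
            for pre in self.row_sets[k]:
                if len(pre) != k + 1 or any(
                    not 0 <= i < n for i, n in zip(pre, mode_sizes)
                ):
                    raise ValueError(f"invalid prefix {pre} at boundary {k}")
            for suf in self.col_sets[k]:
                if len(suf) != d - k - 1 or any(
                    not 0 <= i < n for i, n in zip(suf, mode_sizes[k + 1:])
                ):
                    raise ValueError(f"invalid suffix {suf} at boundary {k}")

    def inject(self, idx: tuple[int, ...], cap: int) -> None:
        """Split a full multi-index into prefixes/suffixes and merge them
        into every boundary's interpolation sets (newest kept under ``cap``)."""
        d = len(idx)
        for k in range(d - 1):
            _merge(self.row_sets[k], idx[: k + 1], cap)
            _merge(self.col_sets[k], idx[k + 1:], cap)


def _dedup(seq: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    seen: dict[tuple[int, ...], None] = {}
    for x in seq:
        seen.setdefault(x, None)
    return list(seen)


def _merge(dest: list[tuple[int, ...]], item: tuple[int, ...], cap: int) -> None:
    if item in dest:
        return
    dest.append(item)
    while len(dest) > cap:
        dest.pop(0)  # drop oldest


def tt_cross_interpolate(
    f: ImplicitTensor,
    r_max: int,
    state: CrossState | None = None,
    rng: np.random.Generator | None = None,
    sweeps: int = 2,
) -> tuple[TensorTrain, CrossState]:
    """Cross-interpolate an implicit tensor with TT-ranks <= ``r_max``.

    One sweep = a right-to-left pass refreshing the column (suffix) sets
    by maxvol on the unfolding columns, followed by a left-to-right pass
    that rebuilds the row (prefix) sets and assembles interpolative
    cores.  The interpolant is exact at the crossed entries, and exact
    everywhere when the tensor's TT-ranks are <= ``r_max`` and the sets
    have captured the unfolding ranks.  Cost per sweep is
    ``O(d * n * r_max^2)`` oracle evaluations.
    """
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    modes = f.mode_sizes
    d = f.d
    if rng is None:
        rng = np.random.default_rng(0)
    if state is None or not state.row_sets:
        state = CrossState(
            row_sets=CrossState.random_init(modes, r_max, rng).row_sets,
            col_sets=CrossState.random_init(modes, r_max, rng).col_sets,
            best_points=state.best_points if state else [],
            iteration=state.iteration if state else 0,
        )
    state.validate(modes)
    _top_up_sets(state, modes, r_max, rng)

    if d == 1:
        vals = np.array([f((i,)) for i in range(modes[0])])
        return TensorTrain([vals.reshape(1, modes[0], 1)]), state

    cores: list[np.ndarray] = []
    for _ in range(max(1, sweeps)):
        _sweep_right_to_left(f, r_max, state)
        cores = _sweep_left_to_right(f, r_max, state)
    return TensorTrain(cores), state


def _top_up_sets(
    state: CrossState,
    modes: tuple[int, ...],
    r_max: int,
    rng: np.random.Generator,
) -> None:
    """Grow undersized interpolation sets with distinct random points so
    the achievable rank is not capped by seeding collisions."""
    d = len(modes)
    for k in range(d - 1):
        for sets, dims in ((state.row_sets[k], modes[: k + 1]),
                           (state.col_sets[k], modes[k + 1:])):
            capacity = int(np.prod(dims)) if dims else 1
            want = min(r_max, capacity)
            have = set(sets)
            attempts = 0
            while len(have) < want and attempts < 50 * want:
                cand = tuple(int(rng.integers(0, n)) for n in dims)
                attempts += 1
                if cand not in have:
                    have.add(cand)
                    sets.append(cand)


def _eval_block(
    f: ImplicitTensor,
    rows: list[tuple[int, ...]],
    cols: list[tuple[int, ...]],
) -> np.ndarray:
    m = np.empty((len(rows), len(cols)))
    for a, pre in enumerate(rows):
        for b, suf in enumerate(cols):
            m[a, b] = f(pre + suf)
    return m


def _orth_cols(m: np.ndarray, r: int) -> np.ndarray:
    """Orthonormal basis (up to r columns) of the column space of m."""
    q, _ = np.linalg.qr(m)
    return q[:, : min(r, q.shape[1])]


def _sweep_right_to_left(f: ImplicitTensor, r_max: int, state: CrossState) -> None:
    d = f.d
    modes = f.mode_sizes
    suffixes: list[tuple[int, ...]] = [()]
    for k in range(d - 1, 0, -1):
        rows = state.row_sets[k - 1]
        cols_full = [(i,) + suf for i in range(modes[k]) for suf in suffixes]
        m = _eval_block(f, rows, cols_full)
        q = _orth_cols(m.T, min(r_max, len(rows)))
        sel = maxvol(q)
        suffixes = [cols_full[s] for s in sel]
        state.col_sets[k - 1] = list(suffixes)


def _sweep_left_to_right(
    f: ImplicitTensor, r_max: int, state: CrossState
) -> list[np.ndarray]:
    d = f.d
    modes = f.mode_sizes
    prefixes: list[tuple[int, ...]] = [()]
    cores: list[np.ndarray] = []
    for k in range(d):
        rows_full = [pre + (i,) for pre in prefixes for i in range(modes[k])]
        cols = state.col_sets[k] if k < d - 1 else [()]
        m = _eval_block(f, rows_full, cols)
        if k < d - 1:
            q = _orth_cols(m, min(r_max, len(cols)))
            sel = maxvol(q)
            core = np.linalg.solve(q[sel].T, q.T).T  # q @ inv(q[sel])
            cores.append(core.reshape(len(prefixes), modes[k], q.shape[1]))
            prefixes = [rows_full[s] for s in sel]
            state.row_sets[k] = list(prefixes)
        else:
            cores.append(m.reshape(len(prefixes), modes[k], 1))
    return cores


# ---------------------------------------------------------------------------
# Magnitude maximization (the global-optimization loop)
# ---------------------------------------------------------------------------


def tt_magnitude_maximize(
    f: ImplicitTensor,
    r_max: int,
    iterations: int,
    refine: Callable[[tuple[int, ...]], tuple[int, ...]] | None = None,
    seed: int = 0,
    refine_top: int | None = None,
    set_cap: int | None = None,
    explore: int = 2,
) -> tuple[tuple[int, ...], float, list[tuple[tuple[int, ...], float]]]:
    """Find the largest-magnitude tensor entry by iterated cross interpolation.

    Per iteration: (1-3) cross-interpolate with the current interpolation
    sets, which concentrates evaluations on large-magnitude entries;
    (4) hand the top ``refine_top`` harvested points to the optional
    ``refine`` callback (a local search owned by the caller, returning a
    grid point) and evaluate the refined points; (5-6) merge refined and
    best-so-far points back into every unfolding's interpolation sets,
    plus ``explore`` random kick points per iteration that keep the sets
    from collapsing onto one basin.  TT-ranks start at ``min(2, r_max)``
    and grow by one per iteration up to ``r_max``.

    Returns the best multi-index, its value, and the full evaluation log
    in evaluation order.  Deterministic for a fixed seed.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if refine_top is None:
        refine_top = r_max
    if set_cap is None:
        set_cap = 2 * r_max

    rng = np.random.default_rng(seed)
    rec = ImplicitTensor(f, f.mode_sizes, record_log=True)
    state = CrossState.random_init(f.mode_sizes, min(2, r_max), rng)

    n_best_kept = max(10, 2 * r_max)
    for it in range(iterations):
        r_t = min(min(2, r_max) + it, r_max)
        log_start = len(rec.log)
        _, state = tt_cross_interpolate(rec, r_t, state, rng, sweeps=1)

        # step 3-4: harvest the largest-magnitude points of this pass
        fresh = rec.log[log_start:]
        fresh_sorted = sorted(fresh, key=lambda p: -abs(p[1]))
        harvested: list[tuple[int, ...]] = []
        for idx, _ in fresh_sorted:
            if idx not in harvested:
                harvested.append(idx)
            if len(harvested) >= refine_top:
                break
        if refine is not None:
            for idx in harvested:
                refined = tuple(int(i) for i in refine(idx))
                rec(refined)  # add the projection to the tensor's point log
                state.inject(refined, set_cap)

        # steps 5-6: merge harvested and global best points into all sets
        for idx in harvested:
            state.inject(idx, set_cap)
        for _ in range(explore):  # random kick points keep sets diverse
            state.inject(tuple(int(rng.integers(0, n))
                               for n in f.mode_sizes), set_cap)
        # refresh best_points from the full log (largest magnitude first)
        seen_vals: dict[tuple[int, ...], float] = {}
        for idx, val in rec.log:
            seen_vals.setdefault(idx, val)
        ranked = sorted(seen_vals.items(), key=lambda p: -abs(p[1]))
        state.best_points = ranked[:n_best_kept]
        for idx, _ in state.best_points[:r_max]:
            state.inject(idx, set_cap)
        state.iteration = it + 1

    best_idx, best_val = state.best_points[0]
    return best_idx, best_val, rec.log
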