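"""The docking loop: energy magnitude transform, rough in-loop
refinement, and the tensor-train global search over the DOF grid.

Minimization is turned into magnitude maximization through

    f(x, E*) = exp(100 arccot(E(x) - E*))

where ``E*`` is the lowest raw energy found so far.  ``arccot`` is the
continuous decreasing branch onto (0, pi), so ``f`` is strictly
decreasing in the energy, maps the current best to ``exp(50 pi)``,
flattens huge clash energies toward 1, and stretches the low-energy end
apart — exactly what a magnitude-maximizing tensor sampler needs.

Each outer iteration cross-interpolates the implicit tensor (decode ->
energy -> transform), harvests the large-magnitude interpolation points,
refines them by a bounded derivative-free simplex search in DOF space
("rough" refinement — the real polishing is done later in
post-processing), stores every refined candidate in an append-only
binary minima store, and re-injects the refined and best points into the
interpolation sets.
"""

from __future__ import annotations

import io
import math
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.optimize

from .config import DockingConfig
from .dof_space import Conformation, SearchSpace, decode, encode
from .molecular_model import EnergyModel, MolecularSystem, validate_energy_model
from .tt_core import ImplicitTensor, tt_magnitude_maximize

__all__ = [
    "energy_transform",
    "rough_refine",
    "dock",
    "MinimaRecord",
    "MinimaStore",
    "TransformState",
]

TRANSFORM_AT_MINIMUM = math.exp(50.0 * math.pi)


@dataclass
class TransformState:
    """Tracks E*, the lowest raw energy seen; non-increasing over a run."""

    e_star: float = math.inf

    def update(self, e: float) -> None:
        if e < self.e_star:
            self.e_star = e


def energy_transform(e: float, e_star: float) -> float:
    """``exp(100 arccot(e - e_star))`` with arccot onto (0, pi).

    Strictly decreasing in ``e``; equals ``exp(50 pi)`` at ``e = e_star``
    and tends to 1 as the energy grows (clashes are flattened).
    """
    arccot = 0.5 * math.pi - math.atan(e - e_star)
    return math.exp(100.0 * arccot)


# ---------------------------------------------------------------------------
# Rough in-loop refinement
# ---------------------------------------------------------------------------


def rough_refine(
    point: Sequence[float],
    space: SearchSpace,
    system: MolecularSystem,
    energy_model: EnergyModel,
    budget: int = 200,
) -> tuple[np.ndarray, float]:
    """Cheap derivative-free local search in DOF space.

    Nelder-Mead simplex over subspace blocks of at most 6 dimensions,
    cycling through the blocks until the evaluation budget is spent or a
    full cycle stalls (the subspace-cycling scheme of subplex-style
    optimizers).  The returned point is clipped to the box and its
    energy never exceeds the input energy.  ``budget`` counts energy
    evaluations; 0 returns the input unchanged.
    """
    p = space.clip_point(np.asarray(point, dtype=float))
    if budget <= 0:
        conf = decode(p, space)
        return p, energy_model.energy(conf.coords)

    used = 0

    def f_full(q: np.ndarray) -> float:
        nonlocal used
        used += 1
        conf = decode(space.clip_point(q), space)
        return energy_model.energy(conf.coords)

    best_p = p.copy()
    best_e = f_full(best_p)
    blocks = [list(range(i, min(i + 6, space.d))) for i in range(0, space.d, 6)]
    widths = (space.upper - space.lower) / np.array(space.mode_sizes)
    stalled = False
    while used < budget and not stalled:
        e_cycle = best_e
        for blk in blocks:
            left = budget - used
            if left <= len(blk) + 1:
                break
            idx = np.array(blk, dtype=int)

            def f_blk(qb: np.ndarray) -> float:
                q = best_p.copy()
                q[idx] = qb
                return f_full(q)

            res = scipy.optimize.minimize(
                f_blk,
                best_p[idx],
                method="Nelder-Mead",
                options={
                    "maxfev": left,
                    "xatol": 1e-4,
                    "fatol": 1e-8,
                    "initial_simplex": _initial_simplex(
                        best_p[idx], widths[idx]),
                },
            )
            if res.fun < best_e:
                best_e = float(res.fun)
                best_p[idx] = res.x
                best_p = space.clip_point(best_p)
        if best_e >= e_cycle - 1e-10:
            stalled = True
    return best_p, best_e


def _initial_simplex(x0: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Simplex scaled to a few grid cells, so the search stays local."""
    k = len(x0)
    s = np.tile(x0, (k + 1, 1))
    for i in range(k):
        s[i + 1, i] += max(2.0 * widths[i], 1e-4)
    return s


# ---------------------------------------------------------------------------
# Binary minima store (.ttm)
# ---------------------------------------------------------------------------

_MAGIC = b"TTM1"
_VERSION = 1


@dataclass
class MinimaRecord:
    point: np.ndarray  # (d,) DOF values
    moveable_coords: np.ndarray  # (n_moveable, 3)
    ligand_coords: np.ndarray  # (n_ligand, 3)
    energy: float  # raw energy, kcal/mol
    iteration: int


class MinimaStore:
    """Append-only little-endian binary file of refined docking candidates.

    Layout: magic ``TTM1``, u16 version, u32 config digest, i64 seed,
    u32 system checksum, u32 d, u32 n_moveable, u32 n_ligand; then per
    record the DOF vector, moveable-atom coordinates, ligand coordinates
    (all f64), the raw energy (f64) and the iteration tag (u32),
    each record followed by the CRC32 of its bytes.
    """

    _HEADER = struct.Struct("<4sHIqIIII")

    def __init__(
        self,
        d: int,
        n_moveable: int,
        n_ligand: int,
        config_digest: int = 0,
        seed: int = 0,
        system_checksum: int = 0,
    ) -> None:
        self.d = d
        self.n_moveable = n_moveable
        self.n_ligand = n_ligand
        self.config_digest = config_digest
        self.seed = seed
        self.system_checksum = system_checksum
        self.records: list[MinimaRecord] = []

    @staticmethod
    def system_checksum_of(system: MolecularSystem) -> int:
        payload = ",".join(a.element for a in system.atoms).encode()
        payload += struct.pack("<II", system.n_receptor, system.n_ligand)
        return zlib.crc32(payload) & 0xFFFFFFFF

    def append(self, record: MinimaRecord) -> None:
        p = np.asarray(record.point, dtype=float).reshape(self.d)
        mv = np.asarray(record.moveable_coords, dtype=float).reshape(
            self.n_moveable, 3)
        lg = np.asarray(record.ligand_coords, dtype=float).reshape(
            self.n_ligand, 3)
        self.records.append(MinimaRecord(p, mv, lg, float(record.energy),
                                         int(record.iteration)))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    # -- serialization ------------------------------------------------------
    def _record_bytes(self, r: MinimaRecord) -> bytes:
        buf = io.BytesIO()
        buf.write(r.point.astype("<f8").tobytes())
        buf.write(r.moveable_coords.astype("<f8").tobytes())
        buf.write(r.ligand_coords.astype("<f8").tobytes())
        buf.write(struct.pack("<dI", r.energy, r.iteration))
        return buf.getvalue()

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            fh.write(self._HEADER.pack(
                _MAGIC, _VERSION, self.config_digest, self.seed,
                self.system_checksum, self.d, self.n_moveable, self.n_ligand))
            for r in self.records:
                payload = self._record_bytes(r)
                fh.write(payload)
                fh.write(struct.pack("<I", zlib.crc32(payload) & 0xFFFFFFFF))

    @classmethod
    def load(cls, path: str | Path, strict: bool = False) -> "MinimaStore":
        """Read a store back; corrupt records are skipped with a count
        unless ``strict``."""
        raw = Path(path).read_bytes()
        if raw[:4] != _MAGIC:
            raise ValueError(f"{path}: not a minima store (bad magic)")
        (magic, version, digest, seed, checksum, d, n_mov, n_lig) = (
            cls._HEADER.unpack_from(raw, 0))
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported store version {version}")
        store = cls(d, n_mov, n_lig, digest, seed, checksum)
        rec_size = 8 * (d + 3 * n_mov + 3 * n_lig) + 12
        off = cls._HEADER.size
        store.n_corrupt = 0
        while off + rec_size + 4 <= len(raw):
            chunk = raw[off:off + rec_size]
            crc = struct.unpack_from("<I", raw, off + rec_size)[0]
            off += rec_size + 4
            if zlib.crc32(chunk) & 0xFFFFFFFF != crc:
                if strict:
                    raise ValueError(f"{path}: corrupt record")
                store.n_corrupt += 1
                continue
            pos = 0
            point = np.frombuffer(chunk, "<f8", d, pos).copy()
            pos += 8 * d
            mv = np.frombuffer(chunk, "<f8", 3 * n_mov, pos).reshape(
                n_mov, 3).copy()
            pos += 24 * n_mov
            lg = np.frombuffer(chunk, "<f8", 3 * n_lig, pos).reshape(
                n_lig, 3).copy()
            pos += 24 * n_lig
            energy, iteration = struct.unpack_from("<dI", chunk, pos)
            store.records.append(MinimaRecord(point, mv, lg, energy, iteration))
        return store

    def to_conformation(
        self, record: MinimaRecord, system: MolecularSystem
    ) -> Conformation:
        """Rebuild a full-complex conformation from a stored record."""
        coords = system.coords()
        for a, i in enumerate(system.moveable_indices):
            coords[i] = record.moveable_coords[a]
        coords[system.n_receptor:] = record.ligand_coords
        return Conformation(point=record.point.copy(), coords=coords,
                            energy=record.energy)


# ---------------------------------------------------------------------------
# The docking driver
# ---------------------------------------------------------------------------


def dock(
    system: MolecularSystem,
    space: SearchSpace,
    energy_model: EnergyModel,
    config: DockingConfig | None = None,
    store_path: str | Path | None = None,
    validate: bool = True,
) -> MinimaStore:
    """Run the TT global search and return the store of refined candidates.

    The implicit tensor is ``grid index -> decode -> energy ->
    magnitude transform``; the refinement callback runs
    :func:`rough_refine` from each harvested point, appends the refined
    candidate to the minima store, lowers ``E*`` when a better raw
    energy appears, and projects the refined point back onto the grid
    for re-injection into the interpolation sets.  Deterministic for a
    fixed seed and config.
    """
    config = config or DockingConfig()
    if validate:
        validate_energy_model(energy_model, system.coords(),
                              seed=config.seed)

    tstate = TransformState()
    raw_cache: dict[tuple[int, ...], float] = {}
    store = MinimaStore(
        d=space.d,
        n_moveable=len(space.moveable),
        n_ligand=system.n_ligand,
        config_digest=config.digest(),
        seed=config.seed,
        system_checksum=MinimaStore.system_checksum_of(system),
    )
    iteration_tag = {"it": 0}

    def evaluator(idx: tuple[int, ...]) -> float:
        e = raw_cache.get(idx)
        if e is None:
            conf = decode(idx, space, grid=True)
            e = energy_model.energy(conf.coords)
            raw_cache[idx] = e
        if not math.isfinite(tstate.e_star):
            tstate.update(e)  # initialize E* from the first evaluated point
        return energy_transform(e, tstate.e_star)

    def refine(idx: tuple[int, ...]) -> tuple[int, ...]:
        p = space.grid_to_point(idx)
        rp, re_ = rough_refine(p, space, system, energy_model,
                               budget=config.refine_budget)
        conf = decode(rp, space)
        store.append(MinimaRecord(
            point=rp,
            moveable_coords=conf.coords[space.moveable].reshape(-1, 3)
            if space.moveable else np.empty((0, 3)),
            ligand_coords=conf.coords[system.n_receptor:],
            energy=re_,
            iteration=iteration_tag["it"],
        ))
        tstate.update(re_)  # E* drops after each refinement completes
        return encode(rp, space)

    f = ImplicitTensor(evaluator, space.mode_sizes)

    # wrap the refine callback to keep an iteration tag in the records
    def refine_tagged(idx: tuple[int, ...]) -> tuple[int, ...]:
        return refine(idx)

    # tt_magnitude_maximize drives iterations internally; expose the tag
    # by counting refinement bursts (refine_top per iteration).
    n_per_iter = (config.refine_top if config.refine_top is not None
                  else config.r_max)

    calls = {"n": 0}

    def refine_counting(idx):
        iteration_tag["it"] = calls["n"] // max(1, n_per_iter)
        calls["n"] += 1
        return refine_tagged(idx)

    tt_magnitude_maximize(
        f,
        r_max=config.r_max,
        iterations=config.iterations,
        refine=refine_counting,
        seed=config.seed,
        refine_top=config.refine_top,
        set_cap=config.set_cap,
    )

    if store_path is not None:
        store.save(store_path)
    return store
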