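"""Stage-II pipeline over the raw docking candidates.

Order of operations, mirroring how the minima spectrum is produced:

1. ``sorter_dedup`` — energy-sort the non-optimized candidates and drop
   near-duplicates by plain (ordered, no symmetry) ligand RMSD.
2. ``optimize_full`` — polish every survivor with L-BFGS-B over the
   Cartesian coordinates of all ligand atoms plus the moveable receptor
   atoms (note the variable change: torsion-space DOFs are only used
   during docking; the polish is free Cartesian with box constraints on
   the moveable atoms).
3. ``unique_dedup`` — re-deduplicate with the symmetry-aware RMSD that
   also includes the moveable receptor atoms, producing the 1-based,
   energy-sorted :class:`MinimaSpectrum`.
4. ``paradigm_indices`` — the INON / EN docking-paradigm indices against
   the locally optimized native pose; ``report`` writes the final table.

Chemical symmetry is handled by a per-atom "chemical digest": the CRC32
of the force-field types of the atom's bonded neighborhood, collected
breadth-first out to 13 bonds and ordered by (bond distance, type).
Graph-automorphic atoms (the two phenyl ortho carbons, say) share a
digest, so the Hungarian assignment within each digest group removes
pseudo-differences such as a phenyl flip from the RMSD.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.optimize

from .config import DockingConfig
from .dof_space import Conformation, SearchSpace
from .docking_engine import MinimaRecord, MinimaStore
from .molecular_model import EnergyModel, MolecularSystem

__all__ = [
    "SpectrumEntry",
    "MinimaSpectrum",
    "ParadigmIndices",
    "plain_rmsd",
    "sorter_dedup",
    "optimize_full",
    "chemical_digest",
    "digest_table",
    "symmetry_rmsd",
    "unique_dedup",
    "paradigm_indices",
    "annotate_spectrum",
    "report",
    "run_pipeline",
]

DIGEST_DEPTH = 13


# ---------------------------------------------------------------------------
# Spectrum containers
# ---------------------------------------------------------------------------


@dataclass
class SpectrumEntry:
    index: int  # 1-based energy rank; the global minimum has index 1
    energy: float
    conformation: Conformation
    rmsd_to_native: float | None = None
    center_distance_to_native: float | None = None


@dataclass
class MinimaSpectrum:
    entries: list[SpectrumEntry] = field(default_factory=list)

    @property
    def n_tot(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


@dataclass
class ParadigmIndices:
    """1-based indices into the energy-sorted spectrum; ``inf`` when no
    entry qualifies.  ``inon = 1`` means the docking paradigm holds."""

    inon: float
    en: float

    @property
    def paradigm_satisfied(self) -> bool:
        return self.inon == 1


# ---------------------------------------------------------------------------
# Plain RMSD + Sorter
# ---------------------------------------------------------------------------


def plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Ordered atom-to-atom RMSD, no symmetry accounting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets differ in shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def sorter_dedup(
    store: MinimaStore | Iterable[MinimaRecord],
    threshold: float = 0.1,
) -> list[MinimaRecord]:
    """Energy-sort the raw candidates and keep, among candidates whose
    plain ligand RMSD is below ``threshold``, only the lowest-energy one
    (greedy ascending-energy sweep; ties by discovery order)."""
    records = list(store)
    order = sorted(range(len(records)), key=lambda i: (records[i].energy, i))
    kept: list[MinimaRecord] = []
    for i in order:
        r = records[i]
        if all(plain_rmsd(r.ligand_coords, k.ligand_coords) >= threshold
               for k in kept):
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# Full local optimization (the polish)
# ---------------------------------------------------------------------------


def optimize_full(
    conformation: Conformation,
    system: MolecularSystem,
    energy_model: EnergyModel,
    space: SearchSpace | None = None,
    gtol: float = 1e-4,
    maxiter: int = 2000,
) -> Conformation:
    """L-BFGS-B over Cartesian coordinates of ligand + moveable atoms.

    Moveable receptor atoms keep their box constraints (their small
    cubes) when a search space is given; ligand atoms are free.  Falls
    back to numerical gradients with a warning if the backend has none.
    Converges at projected-gradient max-norm <= ``gtol`` kcal/mol/A and
    never returns a higher energy than the input.
    """
    import warnings

    x0 = np.array(conformation.coords, dtype=float)
    free = list(system.moveable_indices) + list(system.ligand_index_range)
    free = np.array(free, dtype=int)

    bounds: list[tuple[float, float]] | None = None
    if space is not None and space.moveable:
        half = space.atom_cube_edge / 2.0
        bounds = []
        for i in space.moveable:
            ref = system.receptor_atoms[i].coords
            bounds += [(ref[a] - half, ref[a] + half) for a in range(3)]
        bounds += [(-np.inf, np.inf)] * (3 * system.n_ligand)

    use_grad = energy_model.has_gradient
    if not use_grad:
        warnings.warn("energy backend provides no gradient; "
                      "falling back to numerical differentiation",
                      RuntimeWarning, stacklevel=2)

    def fun(v: np.ndarray):
        x = x0.copy()
        x[free] = v.reshape(-1, 3)
        if use_grad:
            e, g = energy_model.energy_and_gradient(x)
            return e, g[free].ravel()
        return energy_model.energy(x)

    res = scipy.optimize.minimize(
        fun,
        x0[free].ravel(),
        jac=use_grad,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "gtol": gtol * 1e-2, "ftol": 1e-12},
    )
    e_in = (conformation.energy if conformation.energy is not None
            else energy_model.energy(x0))
    x_new = x0.copy()
    x_new[free] = res.x.reshape(-1, 3)
    e_new = float(res.fun)
    if e_new > e_in:  # line-search failure: keep the better iterate
        return Conformation(point=conformation.point.copy(), coords=x0,
                            energy=float(e_in))
    return Conformation(point=conformation.point.copy(), coords=x_new,
                        energy=e_new)


# ---------------------------------------------------------------------------
# Chemical digest + symmetry RMSD
# ---------------------------------------------------------------------------


def chemical_digest(
    system: MolecularSystem, atom_index: int, depth: int = DIGEST_DEPTH
) -> int:
    """CRC32 of the typed bonded neighborhood of a ligand atom.

    The neighborhood (the atom itself included) is collected
    breadth-first out to ``depth`` bonds and ordered by (bond distance
    ascending, force-field type ascending, neighbor-type multiset) —
    the multiset recursion only breaks ties whose members would
    otherwise serialize in arbitrary order; remaining ties contribute
    identical bytes.  Types serialize as one unsigned byte each (types
    1..99; values above 255 are rejected).
    """
    if atom_index not in system.ligand_index_range:
        raise IndexError(f"atom {atom_index} is not a ligand atom")
    g = system.ligand_graph()
    atoms = system.atoms
    dist = nx.single_source_shortest_path_length(g, atom_index, cutoff=depth)

    def type_of(a: int) -> int:
        t = atoms[a].ff_type
        if not 1 <= t <= 255:
            raise ValueError(f"ff_type {t} does not fit in one byte")
        return t

    def nbr_multiset(a: int) -> tuple[int, ...]:
        return tuple(sorted(type_of(b) for b in g.neighbors(a)))

    ordered = sorted(dist, key=lambda a: (dist[a], type_of(a), nbr_multiset(a)))
    payload = bytes(type_of(a) for a in ordered)
    return zlib.crc32(payload) & 0xFFFFFFFF


def digest_table(system: MolecularSystem, depth: int = DIGEST_DEPTH) -> dict[int, int]:
    """Digest of every ligand atom (global index -> 32-bit digest)."""
    return {i: chemical_digest(system, i, depth)
            for i in system.ligand_index_range}


def symmetry_rmsd(
    conf_a: Conformation | np.ndarray,
    conf_b: Conformation | np.ndarray,
    system: MolecularSystem,
    include_moveable: bool = False,
    depth: int = DIGEST_DEPTH,
) -> float:
    """RMSD with approximate chemical-symmetry accounting.

    Ligand atoms sharing a chemical digest form a group; within each
    group the squared-distance matrix between the two conformations is
    assigned optimally (Hungarian method), so symmetry-equivalent atoms
    may swap.  With ``include_moveable`` the moveable receptor atoms
    enter as identity pairs (no permutation).  Never exceeds the naive
    ordered RMSD.
    """
    xa = _full_coords(conf_a, system)
    xb = _full_coords(conf_b, system)
    digests = digest_table(system, depth)
    groups: dict[int, list[int]] = {}
    for i, dig in digests.items():
        groups.setdefault(dig, []).append(i)
    total = 0.0
    count = 0
    for members in groups.values():
        ia = np.array(members, dtype=int)
        if len(ia) == 1:
            total += float(np.sum((xa[ia[0]] - xb[ia[0]]) ** 2))
        else:
            cost = np.sum(
                (xa[ia][:, None, :] - xb[ia][None, :, :]) ** 2, axis=2)
            ri, ci = scipy.optimize.linear_sum_assignment(cost)
            total += float(cost[ri, ci].sum())
        count += len(ia)
    if include_moveable:
        for i in system.moveable_indices:
            total += float(np.sum((xa[i] - xb[i]) ** 2))
            count += 1
    return math.sqrt(total / count)


def _full_coords(conf, system: MolecularSystem) -> np.ndarray:
    if isinstance(conf, Conformation):
        return conf.coords
    x = np.asarray(conf, dtype=float)
    if x.shape == (system.n_atoms, 3):
        return x
    if x.shape == (system.n_ligand, 3):
        full = system.coords()
        full[system.n_receptor:] = x
        return full
    raise ValueError(f"cannot interpret coordinates of shape {x.shape}")


# ---------------------------------------------------------------------------
# Unique + indices + report
# ---------------------------------------------------------------------------


def unique_dedup(
    optimized: Sequence[Conformation],
    threshold: float,
    system: MolecularSystem,
) -> MinimaSpectrum:
    """Greedy ascending-energy sweep with the symmetry-aware RMSD that
    includes the moveable receptor atoms; survivors get contiguous
    1-based indices (the lowest-energy minimum has index 1)."""
    order = sorted(range(len(optimized)),
                   key=lambda i: (optimized[i].energy, i))
    kept: list[Conformation] = []
    for i in order:
        c = optimized[i]
        if all(symmetry_rmsd(c, k, system, include_moveable=True) >= threshold
               for k in kept):
            kept.append(c)
    return MinimaSpectrum(entries=[
        SpectrumEntry(index=r + 1, energy=float(c.energy), conformation=c)
        for r, c in enumerate(kept)
    ])


def paradigm_indices(
    spectrum: MinimaSpectrum,
    optimized_native: Conformation,
    system: MolecularSystem,
    rmsd_cut: float = 2.0,
    energy_window: float = 1.0,
) -> ParadigmIndices:
    """INON / EN against the locally optimized native pose.

    INON: lowest index whose ligand symmetry-RMSD to the optimized
    native is < ``rmsd_cut`` (A); inf if none.  EN additionally requires
    the entry's energy within +/- ``energy_window`` kcal/mol of the
    optimized-native energy; inf if none.
    """
    inon: float = math.inf
    en: float = math.inf
    e_nat = optimized_native.energy
    if e_nat is None:
        raise ValueError("optimized native conformation has no energy")
    for entry in spectrum:
        r = symmetry_rmsd(entry.conformation, optimized_native, system,
                          include_moveable=False)
        if r < rmsd_cut:
            if inon == math.inf:
                inon = entry.index
            if abs(entry.energy - e_nat) <= energy_window:
                en = entry.index
                break
    return ParadigmIndices(inon=inon, en=en)


def annotate_spectrum(
    spectrum: MinimaSpectrum,
    optimized_native: Conformation,
    system: MolecularSystem,
) -> MinimaSpectrum:
    """Fill per-entry RMSD-to-native and ligand-center distance."""
    nat_center = optimized_native.ligand_center(system)
    for entry in spectrum:
        entry.rmsd_to_native = symmetry_rmsd(
            entry.conformation, optimized_native, system,
            include_moveable=False)
        entry.center_distance_to_native = float(np.linalg.norm(
            entry.conformation.ligand_center(system) - nat_center))
    return spectrum


def report(
    spectrum: MinimaSpectrum,
    indices: ParadigmIndices,
    path: str | Path | None = None,
    config: DockingConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Results table: index, energy, RMSD to native, center distance.

    Written as TSV with '#' header comments carrying the run config,
    seed, N_tot and the INON/EN indices."""
    df = pd.DataFrame(
        {
            "index": [e.index for e in spectrum],
            "energy_kcal_mol": [e.energy for e in spectrum],
            "rmsd_to_native_A": [e.rmsd_to_native for e in spectrum],
            "center_distance_A": [e.center_distance_to_native
                                  for e in spectrum],
        }
    )
    if path is not None:
        header = [
            f"# N_tot = {spectrum.n_tot}",
            f"# INON = {indices.inon}",
            f"# EN = {indices.en}",
        ]
        if seed is not None:
            header.append(f"# seed = {seed}")
        if config is not None:
            header.append(f"# config = {config.to_json()}")
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            df.to_csv(fh, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def run_pipeline(
    store: MinimaStore,
    system: MolecularSystem,
    space: SearchSpace,
    energy_model: EnergyModel,
    config: DockingConfig | None = None,
    native: Conformation | None = None,
    rmsd_cut: float = 2.0,
    energy_window: float = 1.0,
) -> tuple[MinimaSpectrum, ParadigmIndices, Conformation]:
    """Sorter -> OptmX -> Unique -> RMSD analysis, in one call.

    ``native`` defaults to the input (crystallographic) pose of the
    system; it is itself polished by :func:`optimize_full` before
    serving as the reference.
    """
    config = config or DockingConfig()
    kept = sorter_dedup(store, threshold=config.sorter_threshold)
    optimized = [
        optimize_full(store.to_conformation(r, system), system, energy_model,
                      space=space)
        for r in kept
    ]
    spectrum = unique_dedup(optimized, config.unique_threshold, system)
    if native is None:
        native = Conformation(point=np.zeros(space.d),
                              coords=system.coords(),
                              energy=energy_model.energy(system.coords()))
    opt_native = optimize_full(native, system, energy_model, space=space)
    indices = paradigm_indices(spectrum, opt_native, system,
                               rmsd_cut=rmsd_cut,
                               energy_window=energy_window)
    annotate_spectrum(spectrum, opt_native, system)
    return spectrum, indices, opt_native
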