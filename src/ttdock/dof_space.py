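"""The d-dimensional docking search space and its grid discretization.

Degrees of freedom (in fixed order): 3 translations of the ligand
geometric center inside the docking cube, 3 rigid-body rotation
parameters, one torsion per rotatable ligand bond (ascending bond
index), then x, y, z of every moveable receptor atom (ascending atom
index), each confined to its own small cube around the crystallographic
position.  Total dimension ``d = 6 + n_torsions + 3 * n_moveable``.

Every dimension is discretized into ``n = 2**m`` cells; grid node ``i``
on a dimension with bounds ``[a, b]`` sits at the cell center
``a + (i + 0.5) (b - a) / n``, so no node lies on a box face and the
node <-> cell mapping is a bijection.  Periodic dimensions (torsions,
rotation angles) span the half-open ``[0, 2 pi)``.

Rotation parameterization: rotation axis from an azimuth in ``[0, 2 pi)``
and the cosine of the polar angle in ``[-1, 1]``, plus a spin angle in
``[0, 2 pi)`` about that axis.  The induced measure is not uniform over
SO(3), which is acceptable for optimization (the box covers every
rotation).

Conformation assembly order: ligand torsions are applied to the input
geometry first (root fragment fixed), then the rigid rotation about the
ligand geometric center, then the translation placing the center at the
decoded cube position — this keeps the decoded center *exactly* at the
translation DOFs, so the center-inside-cube invariant is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .config import DockingConfig
from .molecular_model import MolecularSystem, _rodrigues, rotating_side

__all__ = [
    "DOF",
    "SearchSpace",
    "Conformation",
    "build_search_space",
    "decode",
    "encode",
    "mark_moveable_atoms",
    "read_moveable_file",
    "write_moveable_file",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class DOF:
    kind: str  # translation | rotation | torsion | atom_coord
    lower: float
    upper: float
    n: int
    periodic: bool = False
    label: str = ""


@dataclass
class Conformation:
    """A point of the search space together with the full Cartesian
    geometry of the complex it decodes to."""

    point: np.ndarray  # (d,) continuous DOF values
    coords: np.ndarray  # (n_atoms, 3) full complex geometry
    energy: float | None = None

    def ligand_coords(self, system: MolecularSystem) -> np.ndarray:
        return self.coords[system.n_receptor:]

    def ligand_center(self, system: MolecularSystem) -> np.ndarray:
        return self.ligand_coords(system).mean(axis=0)


class SearchSpace:
    """Ordered DOFs with bounds and grid resolution, bound to a system."""

    def __init__(
        self,
        system: MolecularSystem,
        dims: Sequence[DOF],
        cube_center: np.ndarray,
        cube_edge: float,
        atom_cube_edge: float,
    ) -> None:
        self.system = system
        self.dims = list(dims)
        self.cube_center = np.asarray(cube_center, dtype=float).reshape(3)
        self.cube_edge = float(cube_edge)
        self.atom_cube_edge = float(atom_cube_edge)
        self.lower = np.array([dm.lower for dm in self.dims])
        self.upper = np.array([dm.upper for dm in self.dims])
        self.mode_sizes = tuple(dm.n for dm in self.dims)
        self.periodic = np.array([dm.periodic for dm in self.dims])
        # frozen input geometry the DOFs act on
        self._ref_coords = system.coords()
        self._ref_ligand = self._ref_coords[system.n_receptor:].copy()
        self._ref_center = self._ref_ligand.mean(axis=0)
        self.torsion_bonds = list(system.rotatable_bonds)
        self.moveable = list(system.moveable_indices)
        self._torsion_order = _torsion_application_order(system)

    @property
    def d(self) -> int:
        return len(self.dims)

    # -- grid <-> continuous ------------------------------------------------
    def grid_to_point(self, idx: Sequence[int]) -> np.ndarray:
        idx = np.asarray(idx, dtype=int)
        if idx.shape != (self.d,):
            raise ValueError(f"index must have length {self.d}")
        n = np.array(self.mode_sizes)
        if np.any(idx < 0) or np.any(idx >= n):
            raise IndexError(f"grid index {idx.tolist()} out of range")
        return self.lower + (idx + 0.5) * (self.upper - self.lower) / n

    def point_to_grid(self, point: Sequence[float]) -> tuple[int, ...]:
        """Nearest grid node (= containing cell, ties to the lower index)."""
        p = np.asarray(point, dtype=float)
        width = self.upper - self.lower
        v = p.copy()
        v[self.periodic] = self.lower[self.periodic] + np.mod(
            v[self.periodic] - self.lower[self.periodic], width[self.periodic]
        )
        n = np.array(self.mode_sizes)
        i = np.floor((v - self.lower) / width * n).astype(int)
        return tuple(int(x) for x in np.clip(i, 0, n - 1))

    def clip_point(self, point: np.ndarray) -> np.ndarray:
        """Clip a continuous point into the box (periodic dims wrapped)."""
        p = np.asarray(point, dtype=float).copy()
        width = self.upper - self.lower
        p[self.periodic] = self.lower[self.periodic] + np.mod(
            p[self.periodic] - self.lower[self.periodic], width[self.periodic]
        )
        eps = 1e-12 * np.maximum(1.0, np.abs(self.upper))
        np.clip(p, self.lower, self.upper - eps, out=p)
        return p


def _torsion_application_order(system: MolecularSystem) -> list[tuple[int, set[int]]]:
    """Root-to-leaf order of rotatable bonds with, for each, the set of
    ligand atoms on the far-from-root side (the atoms the torsion moves).

    The root is the largest rigid fragment (ties by lowest atom index)
    obtained by deleting all rotatable bonds from the ligand graph.
    """
    lig = set(system.ligand_index_range)
    if not lig or not system.rotatable_bonds:
        return []
    g = system.bond_graph().subgraph(lig).copy()
    rot = {k: (system.bonds[k].i, system.bonds[k].j) for k in system.rotatable_bonds}
    gf = g.copy()
    for i, j in rot.values():
        gf.remove_edge(i, j)
    frags = sorted(nx.connected_components(gf), key=lambda c: (-len(c), min(c)))
    root_frag = frags[0]
    # BFS over the fragment tree, recording bonds in discovery order
    frag_of = {}
    for fi, frag in enumerate(frags):
        for a in frag:
            frag_of[a] = fi
    order: list[int] = []
    seen = {frag_of[min(root_frag)]}
    remaining = dict(rot)
    progress = True
    while remaining and progress:
        progress = False
        # deterministic: ascending bond index within each BFS layer
        layer = []
        for k in sorted(remaining):
            i, j = remaining[k]
            fi, fj = frag_of[i], frag_of[j]
            if (fi in seen) != (fj in seen):
                layer.append((k, fj if fi in seen else fi))
        for k, newf in layer:
            order.append(k)
            seen.add(newf)
            remaining.pop(k)
            progress = True
    order.extend(sorted(remaining))  # unreachable for a connected ligand
    moving_sets = []
    for k in order:
        i, j = rot[k]
        gg = g.copy()
        gg.remove_edge(i, j)
        side_i = nx.node_connected_component(gg, i)
        side = side_i if min(root_frag) not in side_i else nx.node_connected_component(gg, j)
        moving_sets.append((k, set(side)))
    return moving_sets


def build_search_space(
    system: MolecularSystem, config: DockingConfig | None = None
) -> SearchSpace:
    """Assemble the ordered DOF list for a system under a run config.

    The docking cube defaults to being centered at the geometric center
    of the input (native) ligand pose.
    """
    config = config or DockingConfig()
    lig_center = system.ligand_coords().mean(axis=0)
    center = (np.asarray(config.cube_center, dtype=float)
              if config.cube_center is not None else lig_center)
    n = config.n
    half = config.cube_edge / 2.0
    dims: list[DOF] = []
    for ax in "xyz":
        c = center["xyz".index(ax)]
        dims.append(DOF("translation", c - half, c + half, n, label=f"t{ax}"))
    dims.append(DOF("rotation", 0.0, TWO_PI, n, periodic=True, label="rot_azimuth"))
    dims.append(DOF("rotation", -1.0, 1.0, n, label="rot_cospolar"))
    dims.append(DOF("rotation", 0.0, TWO_PI, n, periodic=True, label="rot_spin"))
    for k in system.rotatable_bonds:
        dims.append(DOF("torsion", 0.0, TWO_PI, n, periodic=True,
                        label=f"torsion_bond{k}"))
    ahalf = config.atom_cube_edge / 2.0
    for i in system.moveable_indices:
        pos = system.receptor_atoms[i].coords
        for ax in range(3):
            dims.append(DOF("atom_coord", pos[ax] - ahalf, pos[ax] + ahalf, n,
                            label=f"atom{i}_{'xyz'[ax]}"))
    return SearchSpace(system, dims, center, config.cube_edge,
                       config.atom_cube_edge)


def decode(
    point_or_index: Sequence[float] | Sequence[int],
    space: SearchSpace,
    grid: bool = False,
) -> Conformation:
    """Map a continuous DOF vector (or a grid multi-index with
    ``grid=True``) to the full Cartesian geometry of the complex."""
    if grid:
        point = space.grid_to_point(point_or_index)
    else:
        point = np.asarray(point_or_index, dtype=float)
        if point.shape != (space.d,):
            raise ValueError(f"point must have length {space.d}")
        below = point < space.lower - 1e-9
        above = point > space.upper + 1e-9
        if np.any(below) or np.any(above):
            bad = int(np.argmax(below | above))
            raise ValueError(
                f"DOF {bad} ({space.dims[bad].label}) value {point[bad]} "
                f"outside [{space.lower[bad]}, {space.upper[bad]}]")

    system = space.system
    coords = space._ref_coords.copy()
    lig = space._ref_ligand.copy()

    # 1. torsions, root-to-leaf (root fragment stays put)
    n_tor = len(space.torsion_bonds)
    tor_vals = dict(zip(space.torsion_bonds, point[6:6 + n_tor]))
    off = system.n_receptor
    for bond_k, moving in space._torsion_order:
        b = system.bonds[bond_k]
        in_moving = b.i in moving
        fixed_pivot = b.j if in_moving else b.i
        moving_pivot = b.i if in_moving else b.j
        axis = lig[moving_pivot - off] - lig[fixed_pivot - off]
        axis = axis / np.linalg.norm(axis)
        rot = _rodrigues(axis, float(tor_vals[bond_k]))
        pivot = lig[fixed_pivot - off]
        idx = np.array(sorted(a - off for a in moving), dtype=int)
        lig[idx] = (lig[idx] - pivot) @ rot.T + pivot

    # 2. rigid rotation about the (current) ligand geometric center
    az, cpol, spin = point[3], point[4], point[5]
    spol = math.sqrt(max(0.0, 1.0 - cpol * cpol))
    axis = np.array([spol * math.cos(az), spol * math.sin(az), cpol])
    rot = _rodrigues(axis, float(spin))
    center = lig.mean(axis=0)
    lig = (lig - center) @ rot.T + center

    # 3. translate the center to the decoded cube position
    lig += np.asarray(point[:3]) - lig.mean(axis=0)

    # 4. moveable receptor atoms at decoded absolute positions
    for a, i in enumerate(space.moveable):
        coords[i] = point[6 + n_tor + 3 * a: 6 + n_tor + 3 * a + 3]
    coords[system.n_receptor:] = lig
    return Conformation(point=np.array(point, dtype=float), coords=coords)


def encode(conformation_or_point, space: SearchSpace) -> tuple[int, ...]:
    """Project a conformation (or raw DOF vector) onto the grid: nearest
    node per dimension, ties to the lower index."""
    p = (conformation_or_point.point
         if isinstance(conformation_or_point, Conformation)
         else np.asarray(conformation_or_point, dtype=float))
    return space.point_to_grid(p)


def mark_moveable_atoms(
    receptor: MolecularSystem | Sequence,
    reference_ligand_poses: Sequence[np.ndarray],
    mlt: float,
) -> list[int]:
    """Receptor atoms within the moveable-layer thickness of any
    reference ligand pose.

    An atom is moveable when its distance to at least one ligand atom of
    at least one reference pose is <= ``mlt`` (angstrom).  Ascending,
    deterministic.
    """
    if mlt < 0:
        raise ValueError("mlt must be >= 0")
    poses = [np.asarray(p, dtype=float).reshape(-1, 3)
             for p in reference_ligand_poses]
    if not poses:
        raise ValueError("at least one reference ligand pose is required")
    atoms = (receptor.receptor_atoms
             if isinstance(receptor, MolecularSystem) else list(receptor))
    rec_xyz = np.array([a.coords for a in atoms], dtype=float)
    dmin = np.full(len(atoms), np.inf)
    for pose in poses:
        tree = cKDTree(pose)
        d, _ = tree.query(rec_xyz)
        dmin = np.minimum(dmin, d)
    return [int(i) for i in np.flatnonzero(dmin <= mlt)]


def read_moveable_file(path: str | Path) -> list[int]:
    """One 0-based receptor atom index per line; '#' starts a comment."""
    out: list[int] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(int(line))
    return sorted(set(out))


def write_moveable_file(path: str | Path, indices: Iterable[int]) -> None:
    lines = ["# moveable receptor atom indices (0-based)"]
    lines += [str(int(i)) for i in sorted(set(indices))]
    Path(path).write_text("\n".join(lines) + "\n")
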