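"""Molecular data model, structure I/O, and the energy-backend contract.

The docking engine only ever sees an :class:`EnergyModel`: a callable on
full Cartesian coordinates of the receptor-ligand complex returning the
total energy in kcal/mol (and optionally its analytic gradient).  The
paper-grade backend for such a model is a complete small-molecule force
field like MMFF94; this package ships a self-contained reference force
field (harmonic bonds and angles, cosine torsions, Lennard-Jones 12-6
plus Coulomb in vacuum) so the whole pipeline is testable without any
external parameter sets.  Any backend honouring the contract — finite
energies on non-overlapping geometries, rigid-motion invariance, and a
gradient consistent with finite differences — can be plugged in.

Atom indexing convention: receptor atoms occupy global indices
``0 .. R-1`` in input order, ligand atoms ``R .. R+L-1``; every
coordinate array handled by the package is ``(R+L, 3)`` in angstrom.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "MolecularSystem",
    "EnergyModel",
    "ReferenceForceField",
    "ParameterizationError",
    "load_ff_parameters",
    "reference_energy",
    "detect_rotatable_bonds",
    "apply_torsion",
    "validate_energy_model",
    "read_receptor_pdb",
    "write_receptor_pdb",
    "read_ligand_mol2",
    "write_ligand_mol2",
    "build_system",
    "element_ff_type",
]

COULOMB_KCAL = 332.0637

# Element-derived force-field types for the reference backend (a complete
# MMFF94 typing engine would assign integers 1..99; these coarse types keep
# the chemical-digest machinery identical under either backend).
_ELEMENT_TYPES = {
    "H": 1, "C": 2, "N": 3, "O": 4, "S": 5, "P": 6,
    "F": 7, "Cl": 8, "Br": 9, "I": 10,
}


def element_ff_type(element: str) -> int:
    return _ELEMENT_TYPES.get(element.capitalize(), 99)


class ParameterizationError(KeyError):
    """A required force-field parameter is missing; the message names it."""


# ---------------------------------------------------------------------------
# Atoms and systems
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    element: str
    coords: np.ndarray  # (3,) angstrom
    partial_charge: float = 0.0
    ff_type: int = 0
    owner: str = "ligand"  # receptor | ligand
    moveable: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if self.ff_type == 0:
            self.ff_type = element_ff_type(self.element)
        if self.ff_type < 1:
            raise ValueError("ff_type must be >= 1")
        if self.owner not in ("receptor", "ligand"):
            raise ValueError(f"unknown owner {self.owner!r}")
        if self.owner == "ligand" and self.moveable:
            raise ValueError("ligand atoms carry no moveable flag; "
                             "ligand mobility lives in the search-space DOFs")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.capitalize() == "H"


@dataclass
class Bond:
    i: int
    j: int
    order: str = "1"  # MOL2 bond orders: 1, 2, 3, am, ar
    in_ring: bool = False

    @property
    def is_single(self) -> bool:
        return self.order in ("1", "am")


class MolecularSystem:
    """Receptor + ligand atoms, the bond graph, and derived annotations."""

    def __init__(
        self,
        receptor_atoms: Sequence[Atom],
        ligand_atoms: Sequence[Atom],
        bonds: Iterable[Bond | tuple] = (),
    ) -> None:
        self.receptor_atoms = list(receptor_atoms)
        self.ligand_atoms = list(ligand_atoms)
        for a in self.receptor_atoms:
            if a.owner != "receptor":
                raise ValueError("receptor atom with wrong owner")
        for a in self.ligand_atoms:
            if a.owner != "ligand":
                raise ValueError("ligand atom with wrong owner")
        self.bonds: list[Bond] = []
        for b in bonds:
            if not isinstance(b, Bond):
                b = Bond(*b)
            self.bonds.append(b)
        self._annotate()

    # -- indexing ----------------------------------------------------------
    @property
    def n_receptor(self) -> int:
        return len(self.receptor_atoms)

    @property
    def n_ligand(self) -> int:
        return len(self.ligand_atoms)

    @property
    def n_atoms(self) -> int:
        return self.n_receptor + self.n_ligand

    @property
    def ligand_index_range(self) -> range:
        return range(self.n_receptor, self.n_atoms)

    @property
    def atoms(self) -> list[Atom]:
        return self.receptor_atoms + self.ligand_atoms

    @property
    def moveable_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.receptor_atoms) if a.moveable]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def ligand_coords(self, coords: np.ndarray | None = None) -> np.ndarray:
        c = self.coords() if coords is None else np.asarray(coords)
        return c[self.n_receptor:]

    # -- graph -------------------------------------------------------------
    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        for k, b in enumerate(self.bonds):
            g.add_edge(b.i, b.j, order=b.order, bond_index=k)
        return g

    def ligand_graph(self) -> nx.Graph:
        return self.bond_graph().subgraph(self.ligand_index_range).copy()

    def _annotate(self) -> None:
        g = self.bond_graph()
        lig = set(self.ligand_index_range)
        if lig:
            sub = g.subgraph(lig)
            if not nx.is_connected(sub):
                raise ValueError("ligand bond graph must be connected")
        for b in self.bonds:
            if (b.i in lig) != (b.j in lig):
                raise ValueError("bonds may not cross the receptor/ligand "
                                 "index spaces")
            g.remove_edge(b.i, b.j)
            b.in_ring = nx.has_path(g, b.i, b.j)
            g.add_edge(b.i, b.j)
        self.rotatable_bonds = detect_rotatable_bonds(self)

    def set_moveable(self, receptor_indices: Iterable[int]) -> None:
        idx = set(int(i) for i in receptor_indices)
        bad = [i for i in idx if not 0 <= i < self.n_receptor]
        if bad:
            raise IndexError(f"moveable indices out of receptor range: {bad}")
        for i, a in enumerate(self.receptor_atoms):
            a.moveable = i in idx


# ---------------------------------------------------------------------------
# Rotatable bonds and torsion application
# ---------------------------------------------------------------------------


def detect_rotatable_bonds(system: MolecularSystem) -> list[int]:
    """Ligand bonds about which torsional rotation is a degree of freedom.

    A bond qualifies when it is single, not in a ring, and each side of
    the split graph moves at least one heavy (non-hydrogen) atom besides
    the on-axis bond atom itself — pure-hydrogen rotors (methyl,
    hydroxyl) are excluded.  Ascending bond index, deterministic.
    """
    lig = set(system.ligand_index_range)
    g = system.bond_graph().subgraph(lig).copy()
    atoms = system.atoms
    out: list[int] = []
    for k, b in enumerate(system.bonds):
        if b.i not in lig or not b.is_single or b.in_ring:
            continue
        g.remove_edge(b.i, b.j)
        side_i = nx.node_connected_component(g, b.i)
        side_j = nx.node_connected_component(g, b.j)
        g.add_edge(b.i, b.j)
        ok = True
        for side, pivot in ((side_i, b.i), (side_j, b.j)):
            heavy = [a for a in side if a != pivot and not atoms[a].is_hydrogen]
            if len(side) < 2 or not heavy:
                ok = False
        if ok:
            out.append(k)
    return out


def rotating_side(system: MolecularSystem, bond_index: int) -> tuple[set[int], int, int]:
    """Atoms moved by a torsion: the smaller component (ties to the side
    holding the higher-indexed bond atom).  Returns (moving set, fixed
    pivot, moving pivot)."""
    b = system.bonds[bond_index]
    lig = set(system.ligand_index_range)
    g = system.bond_graph().subgraph(lig).copy()
    g.remove_edge(b.i, b.j)
    side_i = nx.node_connected_component(g, b.i)
    side_j = nx.node_connected_component(g, b.j)
    if len(side_i) < len(side_j):
        moving, fixed_pivot, moving_pivot = side_i, b.j, b.i
    elif len(side_j) < len(side_i):
        moving, fixed_pivot, moving_pivot = side_j, b.i, b.j
    else:
        hi = max(b.i, b.j)
        lo = min(b.i, b.j)
        moving = side_i if hi == b.i else side_j
        fixed_pivot, moving_pivot = lo, hi
    return set(moving), fixed_pivot, moving_pivot


def apply_torsion(
    coords: np.ndarray,
    bond_index: int,
    angle: float,
    system: MolecularSystem,
) -> np.ndarray:
    """Rotate the smaller side of a rotatable bond by ``angle`` (radians).

    Right-handed rotation about the axis from the fixed-side bond atom to
    the moving-side bond atom; the root side is untouched.
    """
    if bond_index not in system.rotatable_bonds:
        raise ValueError(f"bond {bond_index} is not rotatable")
    moving, fixed_pivot, moving_pivot = rotating_side(system, bond_index)
    out = np.array(coords, dtype=float)
    axis = out[moving_pivot] - out[fixed_pivot]
    axis = axis / np.linalg.norm(axis)
    rot = _rodrigues(axis, angle)
    pivot = out[fixed_pivot]
    moving = sorted(moving - {moving_pivot, fixed_pivot}) + [moving_pivot]
    idx = np.array(sorted(set(moving)), dtype=int)
    out[idx] = (out[idx] - pivot) @ rot.T + pivot
    return out


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.asarray(axis, dtype=float)
    kx, ky, kz = k
    km = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + math.sin(angle) * km + (1.0 - math.cos(angle)) * (km @ km)


# ---------------------------------------------------------------------------
# Energy model contract
# ---------------------------------------------------------------------------


class EnergyModel:
    """Contract: ``energy(coords) -> float`` and, when ``has_gradient``,
    ``energy_and_gradient(coords) -> (float, (N,3) array)``, kcal/mol and
    kcal/mol/angstrom, rigid-motion invariant and finite for
    non-overlapping geometries."""

    has_gradient: bool = False

    def energy(self, coords: np.ndarray) -> float:  # pragma: no cover
        raise NotImplementedError

    def energy_and_gradient(
        self, coords: np.ndarray
    ) -> tuple[float, np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, coords: np.ndarray) -> float:
        return self.energy(coords)


def load_ff_parameters(path: str | Path | None = None) -> dict:
    """Load the packaged (or a user-supplied) TOML parameter table."""
    if path is None:
        src = resources.files("ttdock").joinpath("data/reference_ff.toml")
        data = src.read_bytes()
    else:
        data = Path(path).read_bytes()
    return tomllib.loads(data.decode())


class ReferenceForceField(EnergyModel):
    """Self-contained classical vacuum force field with analytic gradients.

    ``E = sum k_b (b - b0)^2 + sum k_th (theta - theta0)^2
    + sum V [1 + cos(n phi - phi0)] + sum_pairs 4 eps [(s/r)^12 - (s/r)^6]
    + sum_pairs C q_i q_j / (eps_diel r)``

    over bonds, bond angles, proper dihedrals, and all nonbonded pairs
    except 1-2 and 1-3 neighbours.  Parameters come from a TOML table
    keyed by elements/element pairs; a missing entry raises
    :class:`ParameterizationError` naming the pair.  No nonbonded cutoff
    is applied (exact sums).
    """

    has_gradient = True

    def __init__(self, system: MolecularSystem, params: dict | None = None) -> None:
        self.system = system
        self.params = params if params is not None else load_ff_parameters()
        self._build_terms()

    # -- term construction --------------------------------------------------
    def _lj(self, element: str) -> tuple[float, float]:
        tab = self.params.get("lj", {})
        key = element.capitalize()
        if key not in tab:
            raise ParameterizationError(
                f"no Lennard-Jones parameters for element {key!r}")
        return float(tab[key]["sigma"]), float(tab[key]["epsilon"])

    def _bond_param(self, e1: str, e2: str) -> tuple[float, float]:
        tab = self.params.get("bond", {})
        a, b = sorted((e1.capitalize(), e2.capitalize()))
        for key in (f"{a}-{b}", f"{b}-{a}"):
            if key in tab:
                return float(tab[key]["k"]), float(tab[key]["r0"])
        raise ParameterizationError(f"no bond parameters for pair {a}-{b}")

    def _angle_param(self, center: str) -> tuple[float, float]:
        tab = self.params.get("angle", {})
        entry = tab.get(center.capitalize(), tab.get("default"))
        if entry is None:
            raise ParameterizationError(
                f"no angle parameters for center element {center!r}")
        return float(entry["k"]), math.radians(float(entry["theta0"]))

    def _build_terms(self) -> None:
        sys_ = self.system
        atoms = sys_.atoms
        n = sys_.n_atoms
        g = sys_.bond_graph()

        blist, bk, br0 = [], [], []
        for b in sys_.bonds:
            k, r0 = self._bond_param(atoms[b.i].element, atoms[b.j].element)
            blist.append((b.i, b.j))
            bk.append(k)
            br0.append(r0)
        self._bonds = np.array(blist, dtype=int).reshape(-1, 2)
        self._bond_k = np.array(bk)
        self._bond_r0 = np.array(br0)

        alist, ak, at0 = [], [], []
        for j in range(n):
            nbrs = sorted(g.neighbors(j))
            for a_i in range(len(nbrs)):
                for a_k in range(a_i + 1, len(nbrs)):
                    k, t0 = self._angle_param(atoms[j].element)
                    alist.append((nbrs[a_i], j, nbrs[a_k]))
                    ak.append(k)
                    at0.append(t0)
        self._angles = np.array(alist, dtype=int).reshape(-1, 3)
        self._angle_k = np.array(ak)
        self._angle_t0 = np.array(at0)

        tor = self.params.get("torsion", {}).get("default", {})
        self._tor_v = float(tor.get("v", 0.0))
        self._tor_n = int(tor.get("n", 3))
        self._tor_phi0 = math.radians(float(tor.get("phi0", 0.0)))
        tlist = []
        for b in sys_.bonds:
            j, k = b.i, b.j
            for i in sorted(g.neighbors(j)):
                if i == k:
                    continue
                for l in sorted(g.neighbors(k)):
                    if l == j or l == i:
                        continue
                    tlist.append((i, j, k, l))
        self._torsions = np.array(tlist, dtype=int).reshape(-1, 4)

        # nonbonded pairs: all pairs minus 1-2 and 1-3
        excl = set()
        for b in sys_.bonds:
            excl.add((min(b.i, b.j), max(b.i, b.j)))
        for (i, j, k) in self._angles:
            excl.add((min(i, k), max(i, k)))
        ii, jj = np.triu_indices(n, k=1)
        keep = [t for t in zip(ii.tolist(), jj.tolist()) if t not in excl]
        self._pairs = np.array(keep, dtype=int).reshape(-1, 2)
        sig = np.empty(n)
        eps = np.empty(n)
        q = np.empty(n)
        for i, a in enumerate(atoms):
            sig[i], eps[i] = self._lj(a.element)
            q[i] = a.partial_charge
        pi, pj = self._pairs[:, 0], self._pairs[:, 1]
        self._p_sigma = 0.5 * (sig[pi] + sig[pj])
        self._p_eps = np.sqrt(eps[pi] * eps[pj])
        diel = float(self.params.get("general", {}).get("dielectric", 1.0))
        ke = float(self.params.get("general", {}).get(
            "coulomb_constant", COULOMB_KCAL))
        self._p_qq = ke * q[pi] * q[pj] / diel

    # -- evaluation ---------------------------------------------------------
    def energy(self, coords: np.ndarray) -> float:
        return self._eval(np.asarray(coords, dtype=float), want_grad=False)[0]

    def energy_and_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        return self._eval(np.asarray(coords, dtype=float), want_grad=True)

    def _eval(self, x: np.ndarray, want_grad: bool) -> tuple[float, np.ndarray]:
        if x.shape != (self.system.n_atoms, 3):
            raise ValueError(f"coords must be ({self.system.n_atoms}, 3)")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite coordinates")
        e = 0.0
        grad = np.zeros_like(x) if want_grad else None

        if len(self._bonds):
            d = x[self._bonds[:, 0]] - x[self._bonds[:, 1]]
            r = np.linalg.norm(d, axis=1)
            db = r - self._bond_r0
            e += float(np.sum(self._bond_k * db ** 2))
            if want_grad:
                coef = (2.0 * self._bond_k * db / r)[:, None] * d
                np.add.at(grad, self._bonds[:, 0], coef)
                np.add.at(grad, self._bonds[:, 1], -coef)

        if len(self._angles):
            i, j, k = self._angles.T
            u = x[i] - x[j]
            v = x[k] - x[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos = np.sum(u * v, axis=1) / (nu * nv)
            cos = np.clip(cos, -1.0, 1.0)
            th = np.arccos(cos)
            dth = th - self._angle_t0
            e += float(np.sum(self._angle_k * dth ** 2))
            if want_grad:
                sin = np.sqrt(np.clip(1.0 - cos ** 2, 1e-12, None))
                uh = u / nu[:, None]
                vh = v / nv[:, None]
                dth_di = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
                dth_dk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
                pref = (2.0 * self._angle_k * dth)[:, None]
                np.add.at(grad, i, pref * dth_di)
                np.add.at(grad, k, pref * dth_dk)
                np.add.at(grad, j, -pref * (dth_di + dth_dk))

        if len(self._torsions) and self._tor_v != 0.0:
            i, j, k, l = self._torsions.T
            b1 = x[j] - x[i]
            b2 = x[k] - x[j]
            b3 = x[l] - x[k]
            m = np.cross(b1, b2)
            nvec = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            sin_t = np.sum(np.cross(m, nvec) * b2, axis=1) / np.clip(nb2, 1e-12, None)
            cos_t = np.sum(m * nvec, axis=1)
            phi = np.arctan2(sin_t, cos_t)
            arg = self._tor_n * phi - self._tor_phi0
            e += float(np.sum(self._tor_v * (1.0 + np.cos(arg))))
            if want_grad:
                m2 = np.clip(np.sum(m * m, axis=1), 1e-12, None)
                n2 = np.clip(np.sum(nvec * nvec, axis=1), 1e-12, None)
                dphi_di = -(nb2 / m2)[:, None] * m
                dphi_dl = (nb2 / n2)[:, None] * nvec
                t = np.sum(b1 * b2, axis=1) / nb2 ** 2
                s = np.sum(b3 * b2, axis=1) / nb2 ** 2
                dphi_dj = -(1.0 + t)[:, None] * dphi_di + s[:, None] * dphi_dl
                dphi_dk = -(dphi_di + dphi_dj + dphi_dl)
                de = (-self._tor_v * self._tor_n * np.sin(arg))[:, None]
                np.add.at(grad, i, de * dphi_di)
                np.add.at(grad, j, de * dphi_dj)
                np.add.at(grad, k, de * dphi_dk)
                np.add.at(grad, l, de * dphi_dl)

        if len(self._pairs):
            pi, pj = self._pairs.T
            d = x[pi] - x[pj]
            r2 = np.sum(d * d, axis=1)
            r = np.sqrt(r2)
            sr6 = (self._p_sigma ** 2 / r2) ** 3
            sr12 = sr6 ** 2
            e += float(np.sum(4.0 * self._p_eps * (sr12 - sr6)))
            e += float(np.sum(self._p_qq / r))
            if want_grad:
                # dE/dr for LJ + Coulomb, then chain rule through r
                dEdr = (-24.0 * self._p_eps * (2.0 * sr12 - sr6) / r
                        - self._p_qq / r2)
                coef = (dEdr / r)[:, None] * d
                np.add.at(grad, pi, coef)
                np.add.at(grad, pj, -coef)

        return e, (grad if want_grad else np.empty(0))


def reference_energy(
    system: MolecularSystem,
    coords: np.ndarray,
    params: dict | None = None,
    with_gradient: bool = False,
):
    """One-shot reference-force-field evaluation (convenience wrapper)."""
    ff = ReferenceForceField(system, params=params)
    if with_gradient:
        return ff.energy_and_gradient(coords)
    return ff.energy(coords)


def validate_energy_model(
    model: EnergyModel,
    coords: np.ndarray,
    n_checks: int = 5,
    seed: int = 0,
    rigid_tol: float = 1e-6,
    grad_rel_tol: float = 1e-4,
) -> None:
    """Startup validation of an energy backend.

    Checks rigid-motion invariance and (when the backend advertises a
    gradient) agreement with central finite differences on randomly
    perturbed geometries.  Raises ``ValueError`` on violation.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(coords, dtype=float)
    for _ in range(n_checks):
        x = x0 + 0.02 * rng.standard_normal(x0.shape)
        e = model.energy(x)
        if not np.isfinite(e):
            raise ValueError("energy model returned a non-finite energy")
        shift = rng.uniform(-5, 5, 3)
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        rot = _rodrigues(axis, rng.uniform(0, 2 * math.pi))
        center = x.mean(axis=0)
        xr = (x - center) @ rot.T + center + shift
        if abs(model.energy(xr) - e) > rigid_tol * max(1.0, abs(e)):
            raise ValueError("energy model is not rigid-motion invariant")
        if model.has_gradient:
            _, g = model.energy_and_gradient(x)
            h = 1e-5
            for _ in range(6):
                a = rng.integers(0, x.shape[0])
                c = rng.integers(0, 3)
                xp = x.copy()
                xp[a, c] += h
                xm = x.copy()
                xm[a, c] -= h
                fd = (model.energy(xp) - model.energy(xm)) / (2 * h)
                scale = max(1.0, abs(fd), abs(g[a, c]))
                if abs(g[a, c] - fd) > grad_rel_tol * scale:
                    raise ValueError(
                        f"analytic gradient disagrees with finite differences "
                        f"at atom {a} axis {c}: {g[a, c]:.6g} vs {fd:.6g}")


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------


def read_receptor_pdb(path: str | Path) -> list[Atom]:
    """Read receptor atoms (ATOM/HETATM) from a PDB file, file order kept.

    Highest-occupancy / first altLoc wins; hydrogens are expected to be
    present already (inputs are assumed protonated).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("receptor", str(path))
    model = next(structure.get_models())
    atoms: list[Atom] = []
    for atom in model.get_atoms():
        if atom.is_disordered():
            atom = atom.disordered_get()  # highest occupancy representative
        element = (atom.element or atom.get_name()[:1]).capitalize()
        atoms.append(
            Atom(element=element, coords=np.array(atom.get_coord(), dtype=float),
                 owner="receptor", name=atom.get_name())
        )
    if not atoms:
        raise ValueError(f"no atoms read from {path}")
    return atoms


def write_receptor_pdb(
    path: str | Path,
    atoms: Sequence[Atom],
    coords: np.ndarray | None = None,
) -> None:
    """Write receptor atoms as fixed-column PDB (one chain, one residue
    per atom group is not assumed; names are preserved)."""
    xyz = np.array([a.coords for a in atoms]) if coords is None else np.asarray(coords)
    lines = []
    for i, (a, c) in enumerate(zip(atoms, xyz), start=1):
        name = (a.name or a.element)[:4]
        pad_name = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {i:5d} {pad_name}{'':1s}REC A{1:4d}    "
            f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element.upper():>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ligand_mol2(path: str | Path) -> tuple[list[Atom], list[Bond]]:
    """Read a Tripos MOL2 ligand: ATOM block (coords, SYBYL type, charge)
    and BOND block (1-based indices, order)."""
    text = Path(path).read_text()
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        if line.startswith("@<TRIPOS>"):
            current = line.strip()[9:].upper()
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    if "ATOM" not in sections:
        raise ValueError(f"{path}: no @<TRIPOS>ATOM block")
    atoms: list[Atom] = []
    for line in sections["ATOM"]:
        parts = line.split()
        if len(parts) < 6:
            continue
        name, x, y, z, sybyl = parts[1], parts[2], parts[3], parts[4], parts[5]
        charge = float(parts[8]) if len(parts) >= 9 else 0.0
        element = sybyl.split(".")[0].capitalize()
        atoms.append(Atom(element=element, coords=[float(x), float(y), float(z)],
                          partial_charge=charge, owner="ligand", name=name))
    bonds: list[Bond] = []
    for line in sections.get("BOND", []):
        parts = line.split()
        if len(parts) < 4:
            continue
        bonds.append(Bond(int(parts[1]) - 1, int(parts[2]) - 1, parts[3]))
    if not atoms:
        raise ValueError(f"{path}: empty ATOM block")
    return atoms, bonds


def write_ligand_mol2(
    path: str | Path,
    atoms: Sequence[Atom],
    bonds: Sequence[Bond],
    coords: np.ndarray | None = None,
    name: str = "LIG",
) -> None:
    xyz = np.array([a.coords for a in atoms]) if coords is None else np.asarray(coords)
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f"{len(atoms)} {len(bonds)} 0 0 0",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for i, (a, c) in enumerate(zip(atoms, xyz), start=1):
        sybyl = a.element.capitalize()
        lines.append(
            f"{i:7d} {a.name or a.element + str(i):<8s}"
            f"{c[0]:10.4f}{c[1]:10.4f}{c[2]:10.4f} {sybyl:<8s}"
            f"{1:4d} {name:<8s}{a.partial_charge:10.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    for k, b in enumerate(bonds, start=1):
        lines.append(f"{k:6d}{b.i + 1:6d}{b.j + 1:6d} {b.order:>4s}")
    Path(path).write_text("\n".join(lines) + "\n")


def build_system(
    receptor_pdb: str | Path,
    ligand_mol2: str | Path,
    moveable_indices: Iterable[int] = (),
) -> MolecularSystem:
    """Assemble a :class:`MolecularSystem` from structure files.

    Ligand bond indices from the MOL2 file are shifted into the global
    index space (receptor first).
    """
    rec = read_receptor_pdb(receptor_pdb)
    lig, lig_bonds = read_ligand_mol2(ligand_mol2)
    off = len(rec)
    bonds = [Bond(b.i + off, b.j + off, b.order) for b in lig_bonds]
    system = MolecularSystem(rec, lig, bonds)
    system.set_moveable(moveable_indices)
    return system
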