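"""Deterministic toy fixtures: analytic optimization landscapes and
receptor-ligand complexes with planted global minima.

Everything here is a pure function of a spec and a seed, desk-scale by
construction (full brute-force oracles over the coarse grids run in
seconds), and synthetic: the toy complexes emulate the *shape* of a
docking problem — a pocket with a unique low-energy pose, an optional
clash that only receptor-atom motion can relieve — not the energetics of
any real protein-ligand system.

The cavity is a squeezed icosahedral cage of sulfur atoms around a
diatomic carbon ligand lying on the x axis.  The anisotropic squeeze
(y, z scaled by 0.85) makes the planted orientation the unique
well-fitting one.  The clash variant replaces the two on-axis cage
vertices by a blocking sulfur behind the ligand and a clashing hydrogen
in front of it: with a rigid receptor the ligand is trapped against the
block at high strain (no minimum within half an angstrom of the
optimized native), while letting the hydrogen retreat inside its
half-angstrom cube relieves the strain and turns the native basin into
the global minimum.  The toy docking cube (edge 4 A) keeps the search
inside the cage, where those statements were verified by brute force.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import DockingConfig
from .dof_space import Conformation, SearchSpace, build_search_space
from .molecular_model import (
    Atom,
    Bond,
    MolecularSystem,
    write_ligand_mol2,
    write_receptor_pdb,
)
from .tt_core import ImplicitTensor

__all__ = [
    "make_analytic_tensor",
    "ToyComplexSpec",
    "ToyComplex",
    "make_toy_complex",
    "make_random_molecule",
]

DENSE_LIMIT = 300_000


# ---------------------------------------------------------------------------
# Analytic landscapes
# ---------------------------------------------------------------------------


def make_analytic_tensor(
    name: str,
    d: int,
    n: int,
    seed: int = 0,
    require_argmax: bool = True,
) -> tuple[ImplicitTensor, tuple[int, ...] | None]:
    """Analytic positive test tensor plus (where enumerable) its argmax.

    ``separable``: product of positive per-dimension profiles (argmax by
    separability).  ``gaussians``: one dominant and two decoy Gaussian
    bumps on the unit cube.  ``rastrigin-like``: a shifted, negated
    multimodal rastrigin surface (maximum at the grid node nearest the
    origin).  The argmax of the non-separable landscapes is certified by
    a dense scan; requesting it for ``n**d`` beyond ~3e5 entries raises
    (drop ``require_argmax`` or shrink the grid).
    """
    rng = np.random.default_rng(seed)
    grid = (np.arange(n) + 0.5) / n  # cell centers on [0, 1]

    if name == "separable":
        profiles = rng.uniform(0.5, 1.5, size=(d, n))
        argmax = tuple(int(np.argmax(p)) for p in profiles)

        def ev(idx):
            return float(np.prod(profiles[np.arange(d), list(idx)]))

        return ImplicitTensor(ev, (n,) * d), argmax

    if name == "gaussians":
        centers = rng.uniform(0.15, 0.85, size=(3, d))
        amps = np.array([1.0, 0.55, 0.45])
        width = 0.18

        def gval(x: np.ndarray) -> float:
            r2 = np.sum((x[None, :] - centers) ** 2, axis=1)
            return float(np.sum(amps * np.exp(-r2 / (2 * width ** 2))) + 0.01)

        def ev(idx):
            return gval(grid[list(idx)])

        tensor = ImplicitTensor(ev, (n,) * d)
        argmax = _dense_argmax(gval, grid, d, n, require_argmax)
        return tensor, argmax

    if name == "rastrigin-like":
        shift = math.pi  # x in [-1,1]; classic cosine ripples
        amp = 3.0
        offset = d * (1.0 + amp) + 1.0

        def rval(x01: np.ndarray) -> float:
            x = 2.0 * x01 - 1.0
            return float(offset - np.sum(x ** 2 + amp * (1 - np.cos(2 * shift * x))))

        def ev(idx):
            return rval(grid[list(idx)])

        tensor = ImplicitTensor(ev, (n,) * d)
        argmax = _dense_argmax(rval, grid, d, n, require_argmax)
        return tensor, argmax

    raise ValueError(f"unknown analytic tensor {name!r}; "
                     "choose separable | gaussians | rastrigin-like")


def _dense_argmax(fun, grid, d, n, require: bool):
    if n ** d > DENSE_LIMIT:
        if require:
            raise ValueError(
                f"dense certification of the argmax needs n**d = {n ** d} "
                f"evaluations (> {DENSE_LIMIT}); use a smaller grid or pass "
                "require_argmax=False")
        return None
    best_v = -math.inf
    best_i: tuple[int, ...] | None = None
    for idx in itertools.product(range(n), repeat=d):
        v = fun(grid[list(idx)])
        if v > best_v:
            best_v, best_i = v, idx
    return best_i


# ---------------------------------------------------------------------------
# Toy receptor-ligand complexes
# ---------------------------------------------------------------------------


@dataclass
class ToyComplexSpec:
    """Geometry of the synthetic pocket fixture (angstrom).

    The defaults were fixed by brute-force verification of the planted
    global minimum and of the clash construction; they are the study
    conditions of every desk-scale docking experiment in this package.
    """

    n_pocket_atoms: int = 12
    pocket_radius: float = 4.2
    squeeze: float = 0.85  # y/z anisotropy of the cage
    ligand: str = "diatomic"  # diatomic | chain4
    bond_length: float = 1.53
    clash_atom: bool = False
    block_distance: float = 3.1  # blocking wall behind the ligand tip
    clash_distance: float = 1.48  # clashing hydrogen before the other tip
    cube_edge: float = 4.0  # toy docking cube (keeps the search in-cage)
    seed: int = 0


@dataclass
class ToyComplex:
    spec: ToyComplexSpec
    system: MolecularSystem
    planted: Conformation
    config: DockingConfig

    def space(self, config: DockingConfig | None = None) -> SearchSpace:
        return build_search_space(self.system, config or self.config)

    def write_files(self, out_dir: str | Path) -> dict[str, Path]:
        """Materialize receptor PDB + native-pose ligand MOL2."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rec = out / "receptor.pdb"
        lig = out / "ligand.mol2"
        write_receptor_pdb(rec, self.system.receptor_atoms)
        lig_bonds = [Bond(b.i - self.system.n_receptor,
                          b.j - self.system.n_receptor, b.order)
                     for b in self.system.bonds]
        write_ligand_mol2(lig, self.system.ligand_atoms, lig_bonds)
        return {"receptor": rec, "ligand": lig}


def _icosahedron_x(radius: float) -> np.ndarray:
    """Icosahedron vertices at ``radius``, rotated so two lie on the x axis."""
    phi = (1 + 5 ** 0.5) / 2
    verts = []
    for a in (-1, 1):
        for b in (-phi, phi):
            verts += [(0, a, b), (a, b, 0), (b, 0, a)]
    v = np.array(verts, float) / np.linalg.norm((0, 1, phi))
    x0 = np.array((0, 1, phi)) / np.linalg.norm((0, 1, phi))
    ex = np.array([1.0, 0.0, 0.0])
    axis = np.cross(x0, ex)
    axis /= np.linalg.norm(axis)
    ang = math.acos(float(np.dot(x0, ex)))
    kx, ky, kz = axis
    km = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    rot = np.eye(3) + math.sin(ang) * km + (1 - math.cos(ang)) * (km @ km)
    return (v @ rot.T) * radius


def make_toy_complex(spec: ToyComplexSpec | None = None) -> ToyComplex:
    """Build the pocket fixture; the input geometry *is* the planted pose.

    With ``clash_atom`` the construction is checked: the clashing
    hydrogen must strain the planted pose and its retreated position
    (half an angstrom along x) must relieve that strain, otherwise the
    spec is infeasible and a ``ValueError`` with diagnostics is raised.
    """
    spec = spec or ToyComplexSpec()
    verts = _icosahedron_x(spec.pocket_radius).copy()
    verts[:, 1] *= spec.squeeze
    verts[:, 2] *= spec.squeeze
    on_axis = np.abs(np.abs(verts[:, 0]) - spec.pocket_radius) < 1e-6

    receptor: list[Atom] = []
    for i, w in enumerate(verts[: spec.n_pocket_atoms]):
        if spec.clash_atom and on_axis[i]:
            continue  # the on-axis vertices are replaced below
        receptor.append(Atom("S", w, owner="receptor", name=f"S{len(receptor) + 1}"))
    clash_index = None
    if spec.clash_atom:
        tip = spec.bond_length / 2.0
        receptor.append(Atom("S", [-(tip + spec.block_distance), 0.0, 0.0],
                             owner="receptor", name="SB"))
        receptor.append(Atom("H", [tip + spec.clash_distance, 0.0, 0.0],
                             owner="receptor", name="HX"))
        clash_index = len(receptor) - 1

    ligand, lig_bonds = _ligand_template(spec)
    off = len(receptor)
    bonds = [Bond(b.i + off, b.j + off, b.order) for b in lig_bonds]
    system = MolecularSystem(receptor, ligand, bonds)

    config = DockingConfig(cube_edge=spec.cube_edge, seed=spec.seed)
    space = build_search_space(system, config)
    planted_point = np.zeros(space.d)
    planted_point[:3] = space.cube_center
    for a, i in enumerate(system.moveable_indices):
        planted_point[6 + len(system.rotatable_bonds) + 3 * a:
                      6 + len(system.rotatable_bonds) + 3 * a + 3] = (
            system.receptor_atoms[i].coords)
    planted = Conformation(point=planted_point, coords=system.coords())

    if spec.clash_atom:
        _check_clash_feasible(system, clash_index, spec)
    return ToyComplex(spec=spec, system=system, planted=planted, config=config)


def _ligand_template(spec: ToyComplexSpec):
    b = spec.bond_length
    if spec.ligand == "diatomic":
        atoms = [Atom("C", [-b / 2, 0, 0], owner="ligand", name="C1"),
                 Atom("C", [b / 2, 0, 0], owner="ligand", name="C2")]
        bonds = [Bond(0, 1, "1")]
        return atoms, bonds
    if spec.ligand == "chain4":
        # heavy-atom butane-like zig-zag: one rotatable central bond
        half = math.radians((180.0 - 111.0) / 2.0)
        dx, dy = b * math.cos(half), b * math.sin(half)
        pts = np.array([[0.0, 0.0, 0.0], [dx, dy, 0.0],
                        [2 * dx, 0.0, 0.0], [3 * dx, dy, 0.0]])
        pts -= pts.mean(axis=0)
        atoms = [Atom("C", pts[i], owner="ligand", name=f"C{i + 1}")
                 for i in range(4)]
        bonds = [Bond(0, 1, "1"), Bond(1, 2, "1"), Bond(2, 3, "1")]
        return atoms, bonds
    raise ValueError(f"unknown ligand template {spec.ligand!r}")


def _check_clash_feasible(system, clash_index: int, spec: ToyComplexSpec) -> None:
    from .molecular_model import ReferenceForceField

    ff = ReferenceForceField(system)
    x = system.coords()
    e_planted = ff.energy(x)
    x_retreat = x.copy()
    x_retreat[clash_index, 0] = x[clash_index, 0] + 0.5  # cube-face retreat
    e_retreat = ff.energy(x_retreat)
    if not (e_planted > e_retreat + 5.0):
        raise ValueError(
            "infeasible clash construction: planted-pose energy "
            f"{e_planted:.2f} is not relieved by the retreated clash atom "
            f"({e_retreat:.2f}); adjust clash_distance/block_distance")


# ---------------------------------------------------------------------------
# Random small molecules (for symmetry-RMSD stress tests)
# ---------------------------------------------------------------------------


def make_random_molecule(seed: int, n_atoms: int = 8) -> MolecularSystem:
    """Random connected small molecule (tree plus an occasional ring),
    random elements and an arbitrary 3-D embedding; ligand-only system."""
    rng = np.random.default_rng(seed)
    n = int(n_atoms)
    if n < 2:
        raise ValueError("need at least 2 atoms")
    elements = rng.choice(["C", "C", "C", "N", "O", "H"], size=n)
    coords = rng.uniform(-3, 3, size=(n, 3))
    atoms = [Atom(str(elements[i]), coords[i], owner="ligand", name=f"A{i}")
             for i in range(n)]
    bonds = [Bond(int(rng.integers(0, i)), i, "1") for i in range(1, n)]
    if n >= 5 and rng.random() < 0.5:
        existing = {(min(b.i, b.j), max(b.i, b.j)) for b in bonds}
        for _ in range(10):
            i, j = sorted(rng.choice(n, size=2, replace=False).tolist())
            if (i, j) not in existing:
                bonds.append(Bond(i, j, "1"))
                break
    return MolecularSystem([], atoms, bonds)
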