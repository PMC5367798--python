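"""Shared builders for the test suite (all geometry is generated here)."""

import math

import numpy as np
import pytest

from ttdock import (
    Atom,
    Bond,
    MolecularSystem,
    ReferenceForceField,
    make_toy_complex,
    ToyComplexSpec,
)


def build_butane(with_hydrogens: bool = True, seed: int = 1) -> MolecularSystem:
    """Butane-like ligand: heavy chain C1-C2-C3-C4 (+ random hydrogens)."""
    b, ang = 1.53, math.radians(111.0)
    c3 = [1.53 + b * math.cos(math.pi - ang), b * math.sin(math.pi - ang), 0.0]
    heavy = {"C1": [0.0, 0.0, 0.0], "C2": [b, 0.0, 0.0],
             "C3": c3, "C4": [c3[0] + b, c3[1], 0.0]}
    atoms = [Atom("C", xyz, owner="ligand", name=n) for n, xyz in heavy.items()]
    bonds = [Bond(0, 1, "1"), Bond(1, 2, "1"), Bond(2, 3, "1")]
    if with_hydrogens:
        rng = np.random.default_rng(seed)
        h_counts = [(0, 3), (1, 2), (2, 2), (3, 3)]
        idx = 4
        for ci, cnt in h_counts:
            base = np.array(list(heavy.values())[ci])
            for _ in range(cnt):
                d = rng.standard_normal(3)
                d /= np.linalg.norm(d)
                atoms.append(Atom("H", base + 1.09 * d, owner="ligand",
                                  name=f"H{idx}"))
                bonds.append(Bond(ci, idx, "1"))
                idx += 1
    return MolecularSystem([], atoms, bonds)


def build_benzene() -> MolecularSystem:
    """Bare benzene ring (aromatic bonds, no hydrogens)."""
    r = 1.39
    atoms = [Atom("C", [r * math.cos(k * math.pi / 3),
                        r * math.sin(k * math.pi / 3), 0.0],
                  owner="ligand", name=f"C{k + 1}") for k in range(6)]
    bonds = [Bond(k, (k + 1) % 6, "ar") for k in range(6)]
    return MolecularSystem([], atoms, bonds)


def build_toluene() -> MolecularSystem:
    """Toluene with explicit hydrogens: ring C0..C5 (methyl on C0 = C6),
    aromatic H7..H11 on C1..C5, methyl H12..H14."""
    ring = build_benzene()
    atoms = [Atom(a.element, a.coords, owner="ligand", name=a.name)
             for a in ring.ligand_atoms]
    atoms.append(Atom("C", [1.39 + 1.50, 0.0, 0.0], owner="ligand", name="C7"))
    bonds = [Bond(b.i, b.j, b.order) for b in ring.bonds]
    bonds.append(Bond(0, 6, "1"))
    rh = 1.39 + 1.09
    for k in range(1, 6):  # aromatic hydrogens, radially outward in-plane
        atoms.append(Atom("H", [rh * math.cos(k * math.pi / 3),
                                rh * math.sin(k * math.pi / 3), 0.0],
                          owner="ligand", name=f"H{6 + k}"))
        bonds.append(Bond(k, len(atoms) - 1, "1"))
    mc = np.array([1.39 + 1.50, 0.0, 0.0])
    for j, dv in enumerate(([1.0, 0.0, 0.0], [-0.35, 0.8, 0.49],
                            [-0.35, -0.8, 0.49])):
        d = np.array(dv)
        atoms.append(Atom("H", mc + 1.09 * d / np.linalg.norm(d),
                          owner="ligand", name=f"H{12 + j}"))
        bonds.append(Bond(6, len(atoms) - 1, "1"))
    return MolecularSystem([], atoms, bonds)


def build_ethane(seed: int = 0) -> MolecularSystem:
    atoms = [Atom("C", [0, 0, 0], owner="ligand", name="C1"),
             Atom("C", [1.53, 0, 0], owner="ligand", name="C2")]
    bonds = [Bond(0, 1, "1")]
    rng = np.random.default_rng(seed)
    for k in range(6):
        ci = 0 if k < 3 else 1
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        atoms.append(Atom("H", np.array(atoms[ci].coords) + 1.09 * d,
                          owner="ligand", name=f"H{k + 3}"))
        bonds.append(Bond(ci, 2 + k, "1"))
    return MolecularSystem([], atoms, bonds)


@pytest.fixture(scope="session")
def butane():
    return build_butane()


@pytest.fixture(scope="session")
def benzene():
    return build_benzene()


@pytest.fixture(scope="session")
def toluene():
    return build_toluene()


@pytest.fixture(scope="session")
def cavity_toy():
    return make_toy_complex()


@pytest.fixture(scope="session")
def clash_toy():
    return make_toy_complex(ToyComplexSpec(clash_atom=True))


@pytest.fixture(scope="session")
def cavity_ff(cavity_toy):
    return ReferenceForceField(cavity_toy.system)
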