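"""Stage-II pipeline: dedup sweeps, full optimization, chemical digests,
symmetry-aware RMSD, INON/EN indices, report."""

import itertools
import math

import numpy as np
import pytest

from ttdock import (
    Atom,
    Bond,
    Conformation,
    DockingConfig,
    MinimaRecord,
    MinimaStore,
    MolecularSystem,
    ReferenceForceField,
    build_search_space,
    chemical_digest,
    make_random_molecule,
    optimize_full,
    paradigm_indices,
    plain_rmsd,
    report,
    sorter_dedup,
    symmetry_rmsd,
    unique_dedup,
)
from ttdock.postprocess import MinimaSpectrum, SpectrumEntry, digest_table

from conftest import build_toluene


def store_of(records, d=6, n_mov=0, n_lig=2):
    store = MinimaStore(d=d, n_moveable=n_mov, n_ligand=n_lig)
    for r in records:
        store.append(r)
    return store


def rec(lig_coords, energy, d=6):
    lig = np.asarray(lig_coords, dtype=float)
    return MinimaRecord(point=np.zeros(d), moveable_coords=np.empty((0, 3)),
                        ligand_coords=lig, energy=energy, iteration=0)


class TestSorterDedup:
    def test_keep_lowest_of_identical_pair(self):
        lig = [[0, 0, 0], [1.5, 0, 0]]
        store = store_of([rec(lig, -4.0), rec(lig, -5.0)])
        kept = sorter_dedup(store, threshold=0.1)
        assert len(kept) == 1
        assert kept[0].energy == -5.0

    def test_empty_store(self):
        assert sorter_dedup(store_of([])) == []

    def test_pairwise_separation_against_bruteforce(self):
        rng = np.random.default_rng(0)
        records = [rec(rng.uniform(-0.2, 0.2, (2, 3)), rng.uniform(-5, 0))
                   for _ in range(50)]
        kept = sorter_dedup(store_of(records), threshold=0.1)
        # every surviving pair separated
        for a, b in itertools.combinations(kept, 2):
            assert plain_rmsd(a.ligand_coords, b.ligand_coords) >= 0.1
        # quadratic-time reference: greedy sweep in ascending energy
        order = sorted(range(len(records)),
                       key=lambda i: (records[i].energy, i))
        ref = []
        for i in order:
            if all(plain_rmsd(records[i].ligand_coords, records[j].ligand_coords)
                   >= 0.1 for j in ref):
                ref.append(i)
        assert [r.energy for r in kept] == [records[i].energy for i in ref]


class TestOptimizeFull:
    def test_stationary_point_unchanged(self):
        # harmonic diatomic exactly at its equilibrium length (r0 = 1.53)
        sys_ = MolecularSystem(
            [], [Atom("C", [0, 0, 0], owner="ligand"),
                 Atom("C", [1.53, 0, 0], owner="ligand")], [Bond(0, 1, "1")])
        params = {"general": {"dielectric": 1.0},
                  "lj": {"C": {"sigma": 3.4, "epsilon": 0.0}},
                  "bond": {"C-C": {"k": 300.0, "r0": 1.53}},
                  "angle": {"default": {"k": 0.0, "theta0": 109.47}},
                  "torsion": {"default": {"v": 0.0, "n": 3, "phi0": 0.0}}}
        ff = ReferenceForceField(sys_, params=params)
        conf = Conformation(point=np.zeros(6), coords=sys_.coords(),
                            energy=ff.energy(sys_.coords()))
        out = optimize_full(conf, sys_, ff)
        assert np.abs(out.coords - conf.coords).max() < 1e-8

    def test_stretched_diatomic_relaxes_to_equilibrium(self):
        sys_ = MolecularSystem(
            [], [Atom("C", [0, 0, 0], owner="ligand"),
                 Atom("C", [1.83, 0, 0], owner="ligand")], [Bond(0, 1, "1")])
        ff = ReferenceForceField(sys_)
        conf = Conformation(point=np.zeros(6), coords=sys_.coords(),
                            energy=ff.energy(sys_.coords()))
        out = optimize_full(conf, sys_, ff)
        d = np.linalg.norm(out.coords[1] - out.coords[0])
        # bond term dominates; LJ shifts the minimum by < 1e-5
        assert d == pytest.approx(1.53, abs=1e-4)
        assert out.energy < conf.energy

    def test_gradient_norm_at_convergence(self, cavity_toy, cavity_ff):
        rng = np.random.default_rng(1)
        x = cavity_toy.system.coords()
        x[-2:] += 0.3 * rng.standard_normal((2, 3))
        conf = Conformation(point=np.zeros(6), coords=x,
                            energy=cavity_ff.energy(x))
        out = optimize_full(conf, cavity_toy.system, cavity_ff)
        _, g = cavity_ff.energy_and_gradient(out.coords)
        free = list(cavity_toy.system.ligand_index_range)
        assert np.abs(g[free]).max() <= 1e-4
        assert out.energy <= conf.energy


class TestChemicalDigest:
    def test_benzene_carbons_all_equal(self, benzene):
        digs = {chemical_digest(benzene, i) for i in range(6)}
        assert len(digs) == 1

    def test_toluene_ortho_equal_para_distinct(self, toluene):
        # ring indices: 0 attaches the methyl (6); ortho = 1,5; para = 3
        d_ortho1 = chemical_digest(toluene, 1)
        d_ortho2 = chemical_digest(toluene, 5)
        d_para = chemical_digest(toluene, 3)
        d_meta1 = chemical_digest(toluene, 2)
        d_meta2 = chemical_digest(toluene, 4)
        assert d_ortho1 == d_ortho2
        assert d_meta1 == d_meta2
        assert d_para != d_ortho1

    def test_input_order_invariance(self):
        base = build_toluene()
        rng = np.random.default_rng(5)
        perm = rng.permutation(base.n_ligand).tolist()
        inv = {p: i for i, p in enumerate(perm)}
        atoms = [Atom(base.atoms[p].element, base.atoms[p].coords,
                      owner="ligand", name=base.atoms[p].name) for p in perm]
        bonds = [Bond(inv[b.i], inv[b.j], b.order) for b in base.bonds]
        relabeled = MolecularSystem([], atoms, bonds)
        for new_i, old_i in enumerate(perm):
            assert (chemical_digest(relabeled, new_i)
                    == chemical_digest(base, old_i))

    def test_depth_limits_neighborhood(self):
        # two atoms distinguishable only 3 bonds away: shallow digests tie
        chain = [Atom("C", [1.5 * k, 0, 0], owner="ligand", name=f"C{k}")
                 for k in range(5)]
        chain.append(Atom("O", [1.5 * 5, 0, 0], owner="ligand", name="O"))
        bonds = [Bond(k, k + 1, "1") for k in range(5)]
        sys_ = MolecularSystem([], chain, bonds)
        assert (chemical_digest(sys_, 1, depth=1)
                == chemical_digest(sys_, 3, depth=1))
        assert (chemical_digest(sys_, 1, depth=13)
                != chemical_digest(sys_, 3, depth=13))

    def test_is_crc32_of_type_sequence(self, benzene):
        import zlib
        # all six carbons, equidistant shells of identical types:
        # sequence is ff_type(C)=2 repeated 6 times
        assert chemical_digest(benzene, 0) == zlib.crc32(bytes([2] * 6))


def flip_phenyl(system, coords):
    """Rotate the phenyl ring (ring carbons + aromatic hydrogens) 180 deg
    about the attachment (x) axis; the methyl group stays put."""
    out = coords.copy()
    moved = list(range(6)) + list(range(7, 12))
    out[np.ix_(moved, [1, 2])] *= -1.0
    return out


class TestSymmetryRmsd:
    def test_identity_zero(self, toluene):
        x = toluene.coords()
        assert symmetry_rmsd(x, x, toluene) == 0.0

    def test_phenyl_flip_pseudo_difference_removed(self, toluene):
        x = toluene.coords()
        flipped = flip_phenyl(toluene, x)
        naive = plain_rmsd(x, flipped)
        assert naive > 1.0  # a real coordinate difference...
        assert symmetry_rmsd(x, flipped, toluene) <= 1e-6  # ...not chemical

    def test_never_exceeds_naive(self):
        for seed in range(20):
            sys_ = make_random_molecule(seed, n_atoms=8)
            rng = np.random.default_rng(seed + 100)
            xa = sys_.coords()
            xb = xa + 0.5 * rng.standard_normal(xa.shape)
            assert (symmetry_rmsd(xa, xb, sys_)
                    <= plain_rmsd(xa, xb) + 1e-12)

    def test_symmetric_in_arguments(self):
        for seed in range(10):
            sys_ = make_random_molecule(seed, n_atoms=7)
            rng = np.random.default_rng(seed)
            xa = sys_.coords()
            xb = xa + 0.4 * rng.standard_normal(xa.shape)
            assert symmetry_rmsd(xa, xb, sys_) == pytest.approx(
                symmetry_rmsd(xb, xa, sys_), abs=1e-12)

    def test_equals_bruteforce_group_permutation_minimum(self):
        """Hungarian-per-digest-group equals exhaustive enumeration of
        within-group permutations on small random molecules."""
        checked = 0
        for seed in range(40):
            sys_ = make_random_molecule(seed, n_atoms=8)
            groups = {}
            for i, dig in digest_table(sys_).items():
                groups.setdefault(dig, []).append(i)
            if max(len(g) for g in groups.values()) > 4:
                continue
            rng = np.random.default_rng(seed + 1000)
            xa = sys_.coords()
            xb = xa + 0.6 * rng.standard_normal(xa.shape)
            total_best = 0.0
            for members in groups.values():
                best = math.inf
                for perm in itertools.permutations(members):
                    cost = sum(float(np.sum((xa[i] - xb[j]) ** 2))
                               for i, j in zip(members, perm))
                    best = min(best, cost)
                total_best += best
            oracle = math.sqrt(total_best / sys_.n_ligand)
            assert symmetry_rmsd(xa, xb, sys_) == pytest.approx(
                oracle, abs=1e-10)
            checked += 1
        assert checked >= 20

    def test_moveable_atoms_identity_pairs(self):
        rec_atoms = [Atom("S", [5.0, 0, 0], owner="receptor", name="S1")]
        lig = [Atom("C", [0, 0, 0], owner="ligand"),
               Atom("C", [1.5, 0, 0], owner="ligand")]
        sys_ = MolecularSystem(rec_atoms, lig, [Bond(1, 2, "1")])
        sys_.set_moveable([0])
        xa = sys_.coords()
        xb = xa.copy()
        xb[0] += [0.3, 0.0, 0.0]  # only the moveable receptor atom differs
        assert symmetry_rmsd(xa, xb, sys_, include_moveable=False) == 0.0
        expected = math.sqrt(0.3 ** 2 / 3)  # 3 atoms counted, one displaced
        assert symmetry_rmsd(xa, xb, sys_, include_moveable=True) == (
            pytest.approx(expected, abs=1e-12))


class TestUniqueDedupAndIndices:
    def conf(self, sys_, lig_coords, energy):
        x = sys_.coords()
        x[sys_.n_receptor:] = lig_coords
        return Conformation(point=np.zeros(6), coords=x, energy=energy)

    def test_symmetric_duplicates_collapse(self, toluene):
        x = toluene.coords()
        a = self.conf(toluene, x, -3.0)
        b = self.conf(toluene, flip_phenyl(toluene, x), -2.5)
        spectrum = unique_dedup([a, b], 0.1, toluene)
        assert spectrum.n_tot == 1
        assert spectrum.entries[0].energy == -3.0

    def test_distant_poses_survive_with_contiguous_indices(self, toluene):
        x = toluene.coords()
        confs = [self.conf(toluene, x + [0, 0, 5 * k], -1.0 * k)
                 for k in range(4)]
        spectrum = unique_dedup(confs, 0.1, toluene)
        assert spectrum.n_tot == 4
        assert [e.index for e in spectrum] == [1, 2, 3, 4]
        energies = [e.energy for e in spectrum]
        assert energies == sorted(energies)

    def test_idempotent(self, toluene):
        rng = np.random.default_rng(3)
        x = toluene.coords()
        confs = [self.conf(toluene, x + rng.uniform(-0.1, 0.1, x.shape)
                           [toluene.n_receptor:], rng.uniform(-5, 0))
                 for _ in range(12)]
        first = unique_dedup(confs, 0.1, toluene)
        second = unique_dedup([e.conformation for e in first], 0.1, toluene)
        assert [e.energy for e in second] == [e.energy for e in first]

    def test_survivors_pairwise_separated(self, toluene):
        rng = np.random.default_rng(4)
        x = toluene.coords()
        confs = [self.conf(toluene,
                           x[toluene.n_receptor:]
                           + rng.uniform(-0.15, 0.15, (toluene.n_ligand, 3)),
                           rng.uniform(-5, 0)) for _ in range(30)]
        spectrum = unique_dedup(confs, 0.1, toluene)
        for a, b in itertools.combinations(spectrum.entries, 2):
            assert symmetry_rmsd(a.conformation, b.conformation, toluene,
                                 include_moveable=True) >= 0.1

    def test_native_at_rank_one(self, toluene):
        x = toluene.coords()
        native = self.conf(toluene, x, -5.0)
        far = self.conf(toluene, x + [0, 0, 6.0], -4.0)
        spectrum = unique_dedup([native, far], 0.1, toluene)
        idx = paradigm_indices(spectrum, native, toluene)
        assert idx.inon == 1 and idx.en == 1
        assert idx.paradigm_satisfied

    def test_no_entry_near_native_gives_inf(self, toluene):
        x = toluene.coords()
        native = self.conf(toluene, x, -5.0)
        far = self.conf(toluene, x + [0, 0, 8.0], -6.0)
        spectrum = unique_dedup([far], 0.1, toluene)
        idx = paradigm_indices(spectrum, native, toluene, rmsd_cut=2.0)
        assert idx.inon == math.inf and idx.en == math.inf

    def test_energy_window_excludes_en(self, toluene):
        x = toluene.coords()
        native = self.conf(toluene, x, -5.0)
        near_but_hot = self.conf(toluene, x + [0, 0, 1.0], -2.0)
        far_low = self.conf(toluene, x + [0, 0, 9.0], -7.0)
        spectrum = unique_dedup([far_low, near_but_hot], 0.1, toluene)
        idx = paradigm_indices(spectrum, native, toluene,
                               rmsd_cut=2.0, energy_window=1.0)
        assert idx.inon == 2
        assert idx.en == math.inf

    def test_empty_spectrum_both_inf(self, toluene):
        native = self.conf(toluene, toluene.coords(), -5.0)
        idx = paradigm_indices(MinimaSpectrum(), native, toluene)
        assert idx.inon == math.inf and idx.en == math.inf


class TestReport:
    def test_columns_and_counts(self, tmp_path, toluene):
        x = toluene.coords()
        helper = TestUniqueDedupAndIndices()
        confs = [helper.conf(toluene, x + [0, 0, 4.0 * k], -1.0 * k)
                 for k in range(3)]
        spectrum = unique_dedup(confs, 0.1, toluene)
        native = helper.conf(toluene, x, 0.0)
        from ttdock.postprocess import annotate_spectrum
        annotate_spectrum(spectrum, native, toluene)
        idx = paradigm_indices(spectrum, native, toluene)
        path = tmp_path / "report.tsv"
        df = report(spectrum, idx, path=path, seed=11)
        assert list(df.columns) == ["index", "energy_kcal_mol",
                                    "rmsd_to_native_A", "center_distance_A"]
        assert len(df) == spectrum.n_tot
        # center distance equals independent recomputation
        nat_center = x[toluene.n_receptor:].mean(axis=0)
        for entry, got in zip(spectrum, df["center_distance_A"]):
            lig = entry.conformation.coords[toluene.n_receptor:]
            assert got == pytest.approx(
                float(np.linalg.norm(lig.mean(axis=0) - nat_center)),
                abs=1e-12)
        text = path.read_text()
        assert text.startswith("# N_tot = 3")
        assert "# seed = 11" in text

    def test_empty_spectrum_header_only(self, tmp_path, toluene):
        helper = TestUniqueDedupAndIndices()
        native = helper.conf(toluene, toluene.coords(), 0.0)
        idx = paradigm_indices(MinimaSpectrum(), native, toluene)
        path = tmp_path / "empty.tsv"
        df = report(MinimaSpectrum(), idx, path=path)
        assert len(df) == 0
        assert "# N_tot = 0" in path.read_text()
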