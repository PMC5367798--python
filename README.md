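# ttdock

Grid-free flexible-ligand docking by **tensor-train (TT) global
optimization**, with moveable receptor atoms and a symmetry-aware
spectrum of low-energy minima.

## The problem

Docking asks where a small molecule binds a protein. Under the *docking
paradigm*, the native pose sits at (or near) the global minimum of the
protein–ligand energy, so docking becomes global minimization of
`E(x)` over the joint conformational space `x`: the ligand's rigid-body
position and orientation, its torsions about rotatable bonds, and —
when receptor flexibility matters — the Cartesian coordinates of
selected *moveable* receptor atoms. With tens of moveable atoms the
search space reaches a hundred or more dimensions, far beyond grid
scans or pose enumeration, and precalculated energy grids cannot
represent a receptor that changes shape. `ttdock` evaluates the force
field directly at every probed conformation, so receptor motion costs
nothing extra in machinery.

The package is for people studying high-dimensional docking or
low-energy minima spectra of molecular complexes: it provides the
optimizer, the degrees-of-freedom model, a reference energy backend,
the post-processing chain, and deterministic toy fixtures so every
stage is testable on a desk machine.

## The method

Discretize each of the `d` degrees of freedom into `n = 2^m` cells.
The energies on this grid form an implicit `d`-dimensional tensor `A`
with `n^d` entries — far too many to enumerate, but representable in
**tensor-train** form

    A[i_1..i_d] = G_1[:,i_1,:] G_2[:,i_2,:] ... G_d[:,i_d,:],

whose cost grows only linearly in `d` when the TT-ranks `r_k` are
small. **TT-Cross** interpolation builds such a representation from
`O(d n r_max^2)` adaptively chosen entries, steering the selection with
maximal-volume (`maxvol`) submatrices of the unfolding matrices —
which makes it gravitate toward large-magnitude entries. Minimization
is mapped onto magnitude maximization by the transform

    f(x, E*) = exp(100 arccot(E(x) − E*)),

where `E*` is the lowest energy found so far: the current minimum maps
to `exp(50π)`, clashes flatten toward 1, and the low-energy end is
stretched apart. Each outer iteration cross-interpolates the
transformed tensor, harvests the largest-magnitude interpolation
points, refines them with a bounded Nelder–Mead simplex search in DOF
space (subspace-cycling blocks of ≤ 6 dimensions), stores every refined
candidate in a binary minima store (`.ttm`), and re-injects refined and
best points into the interpolation sets.

**Moveable atoms.** A receptor atom is moveable when it lies within the
moveable-layer thickness (MLT, up to 3 Å) of a reference ligand pose;
each moveable atom then gets its own small cube (edge 1 Å, i.e. ± 0.5 Å
about its crystallographic position) and three Cartesian DOFs. The
ligand's geometric center is confined to the docking cube (edge 10 Å by
default, centered on the native ligand).

**Post-processing** turns the raw candidates into a minima spectrum:
an energy-sorted dedup sweep at 0.1 Å plain ligand RMSD; full L-BFGS-B
polishing over the Cartesian coordinates of all ligand atoms plus
moveable receptor atoms; a second dedup using the **symmetry-aware
RMSD** (per-atom 32-bit *chemical digests* — CRC32 of the force-field
types of the bonded neighborhood, breadth-first to depth 13 — group
symmetry-equivalent atoms, and a Hungarian assignment inside each group
removes pseudo-differences such as a phenyl flip); and finally the
docking-paradigm indices against the locally optimized native pose:

* **INON** — index (energy rank) of the first minimum within 2 Å
  symmetry-RMSD of the optimized native pose; `INON = 1` means the
  docking paradigm is satisfied; `inf` means no such minimum was found.
* **EN** — like INON, additionally within ± 1 kcal/mol of the optimized
  native energy.

The energy backend is a contract (energy + optional analytic gradient,
rigid-motion invariant); the shipped reference force field (harmonic
bonds/angles, cosine torsions, Lennard-Jones 12-6 + Coulomb in vacuum,
parameters in a packaged TOML table) satisfies it and keeps the whole
pipeline self-contained. A production-grade force field such as MMFF94
can be plugged in through the same contract.

## Worked example

The toy *clash* fixture is a squeezed icosahedral pocket whose planted
ligand pose is strained by a clashing receptor hydrogen; only letting
that hydrogen retreat (≤ 0.5 Å, inside its cube) relieves the strain.
Dock with the clashing atom moveable:

```sh
ttdock fixtures --name clash1 --out-dir demo/
ttdock dock --receptor demo/receptor.pdb --ligand demo/ligand.mol2 \
    --moveable demo/moveable.txt --cube-edge 4 --grid-bits 5 \
    --rmax 4 --iterations 10 --seed 1 --out demo/run.ttm
ttdock postprocess --store demo/run.ttm --receptor demo/receptor.pdb \
    --ligand demo/ligand.mol2 --moveable demo/moveable.txt \
    --cube-edge 4 --rmsd-cut 0.5 --report demo/report.tsv
```

prints

```
search space: d = 9 (= 6 + 0 torsions + 3*1 moveable atoms; ...)
stored 40 refined candidates -> demo/run.ttm
N_tot = 3  INON = 1  EN = 1
docking paradigm satisfied (INON = 1)
```

and the report table

```
index  energy_kcal_mol  rmsd_to_native_A  center_distance_A
1      -4.760           6.6e-07           2.7e-07
2      -2.584           1.063             0.120
3      -2.584           0.990             0.120
```

Three unique minima were found (`N_tot = 3`); the global minimum
(index 1, −4.76 kcal/mol) coincides with the optimized native pose to
sub-micro-ångström RMSD, so `INON = 1`: the docking paradigm holds.
The two higher minima are the same reoriented pose related by the
diatomic ligand's symmetry axis. Running the same system with a rigid
receptor (`ttdock dock` without `--moveable`) leaves the native basin
strained and unreachable: no minimum lies within the 0.5 Å acceptance
radius and the report shows `INON = inf` — receptor-atom mobility is
what turns the failure into `INON = 1`.

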