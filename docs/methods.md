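# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open, in enough detail
to re-derive the package's behavior.

## Search space and grid

The conformational vector is ordered as: 3 translations of the ligand
geometric center (bounded by the docking cube, default edge 10 Å,
centered on the input ligand's geometric center), 3 rotation parameters,
one torsion per rotatable ligand bond (ascending bond index), then
x, y, z of each moveable receptor atom (ascending atom index), each
bounded by its own cube (default edge 1 Å, i.e. ± 0.5 Å about the
crystallographic position). Hence `d = 6 + n_torsions + 3 n_moveable`.

*Rotation parameterization.* Axis azimuth in `[0, 2π)`, cosine of the
axis polar angle in `[−1, 1]`, and spin angle in `[0, 2π)`. The induced
measure on SO(3) is not uniform; for optimization (as opposed to
sampling) only coverage matters, and this choice gives a rectangular
box with periodic angle dimensions and no coordinate singularities in
the box interior.

*Grid.* Every dimension carries `n = 2^m` cells; node `i` sits at the
cell center `a + (i + 0.5)(b − a)/n`, so no node lies on a box face and
node ↔ cell is a bijection (continuous points project to the containing
cell; ties go to the lower index). Periodic dimensions use the
half-open `[0, 2π)` so node 0 and node n are not duplicates.

*Decoding order.* Torsions are applied to the input geometry first
(root fragment fixed), then the rigid rotation about the ligand
geometric center, then the translation that places the center exactly
at the decoded cube position. Applying the translation last makes the
center-inside-the-cube invariant exact; applying torsions last would
let torsional motion drift the center off the decoded value. The two
orders parameterize the same set of poses.

*Torsion tree.* Rotatable bonds are single, non-ring ligand bonds that
move at least one heavy atom on each side beyond the on-axis atoms —
pure-hydrogen rotors (methyl, hydroxyl) are excluded, consistent with
how docking tools count ligand torsions. The root fragment is the
largest rigid fragment (ties by lowest atom index); torsions apply
root-to-leaf in BFS layers, ascending bond index within a layer.

## Tensor-train global optimization

`maxvol` selects a dominant square submatrix by greedy row swaps (each
swap strictly increases |det|, so the loop terminates at a local volume
maximum) started from several deterministic selections: column-pivoted
QR, LU pivot rows, and four restarts seeded from the matrix content.
The multi-start is what makes the selected volume reliably near the
global maximum at the block sizes used here; a single start converges
to a noticeably sub-maximal single-swap-stable selection on a few
percent of random matrices.

`tt_cross_interpolate` alternates a right-to-left pass that refreshes
the column (suffix) interpolation sets with a left-to-right pass that
rebuilds the row (prefix) sets and assembles interpolative cores; the
interpolant is exact at the crossed entries, and exact everywhere when
the tensor's TT-ranks are within the cap and the sets span the
unfolding spaces. Undersized sets (random seeding can collide) are
topped up with distinct random points before each sweep, so the
achievable rank is never capped by seeding accidents. One pass costs
`O(d n r_max²)` oracle calls; the measured constant is ≈ 1.6 with the
boundary dimensions cheaper than interior ones (their outer index set
is the singleton empty prefix/suffix, so those blocks cost `n·r`, not
`n·r²` — total counts are affine in `d`, proportional only
asymptotically).

`tt_magnitude_maximize` runs the outer loop: cross-interpolate with the
current sets, harvest the largest-magnitude evaluated points, hand the
top `r_max` to the caller's refinement callback, project the refined
points back onto the grid (nearest node, ties to the lower index), and
merge refined, harvested and best-so-far points into every unfolding's
sets (cap `2 r_max`, oldest dropped), plus two random kick points per
iteration. The kick points keep the interpolation sets from collapsing
onto a single basin; without them the optimizer occasionally locks onto
a decoy mode of a multimodal landscape. TT-ranks start at
`min(2, r_max)` and grow by one per iteration — early iterations are
cheap and small ranks suffice on fine grids. Deterministic for a fixed
seed.

## Energy model

The engine sees only the `EnergyModel` contract: `energy(coords)` in
kcal/mol (vacuum), optionally an analytic gradient, rigid-motion
invariant, finite for non-overlapping geometries. Backends are
validated at startup (rigid-motion invariance and, when a gradient is
advertised, agreement with central finite differences at h = 1e−5 Å
within 1e−4 relative on random perturbations).

The shipped reference force field is a deliberately small classical
model: harmonic bonds `k_b (b − b0)²` and angles `k_θ (θ − θ0)²`, one
generic cosine torsion `V [1 + cos(nφ − φ0)]` (V = 0.3 kcal/mol,
n = 3), Lennard-Jones 12-6 with Lorentz–Berthelot combination, and
Coulomb `332.0637 q_i q_j / r` with dielectric 1 (vacuum). 1–2 and 1–3
pairs are excluded; there is no nonbonded cutoff (exact sums — the
systems this package computes on are small). Parameters live in a
packaged TOML table keyed by element (LJ), element pair (bonds), and
central element (angles); a missing entry raises an error naming the
pair. Force-field atom types are element-derived small integers (H=1,
C=2, N=3, O=4, S=5, P=6, halogens 7–10, other 99), one byte each, so
the chemical-digest machinery behaves identically under a richer
backend whose types are 1–99. A complete small-molecule force field
(e.g. MMFF94 via an external library) can be adapted to the contract;
re-implementing one is out of scope here and would add nothing to the
optimizer.

## Docking loop specifics

* `E*` initializes from the first evaluated point and drops after each
  refinement completes; energies below the current `E*` encountered
  mid-pass still transform to finite values (the arccot branch maps
  onto `(0, π)`, so `f < exp(100π) ≈ 1e136`, inside double range).
* Rough refinement is Nelder–Mead over blocks of ≤ 6 DOFs, cycling
  until the 200-evaluation budget (config-exposed) is spent or a full
  cycle stalls; the initial simplex spans about two grid cells per
  dimension so the search stays local. The refined point is clipped to
  the box and its energy never exceeds the input energy. The budget is
  intentionally small: this stage only needs to drop a harvested point
  into its basin — the quasi-Newton polish happens in post-processing.
* Every refined candidate is stored (no energy ceiling); the
  post-processing dedup decides what survives.
* The minima store is a little-endian binary file: magic `TTM1`,
  version, config digest, seed, system checksum, dimensions; then per
  record the DOF vector, moveable-atom and ligand coordinates, raw
  energy, iteration tag, and a CRC32. Corrupt records are skipped (and
  counted) on read unless strict mode is requested.

## Post-processing

* Sorter: ascending-energy greedy sweep, plain ordered ligand RMSD
  (all atoms, hydrogens included), threshold 0.1 Å, keep-lowest.
* Full optimization: L-BFGS-B over Cartesian coordinates of all ligand
  atoms plus moveable receptor atoms (the variable change from torsion
  space to Cartesian is deliberate — the polish must be able to relax
  bond geometry the DOF model holds rigid). Moveable atoms keep their
  box constraints; convergence at projected-gradient max-norm
  ≤ 1e−4 kcal/mol/Å or 2000 iterations; a failed line search returns
  the best iterate.
* Unique: same greedy sweep with the symmetry-aware RMSD including the
  moveable receptor atoms (identity pairs, no permutation). The
  threshold is config-exposed and defaults to the Sorter's 0.1 Å for
  consistency. Energy ties sort stably by discovery order.
* Chemical digest: CRC32 (zlib convention: reflected polynomial
  0xEDB88320, init 0xFFFFFFFF, final xor) of the neighborhood type
  sequence, breadth-first to depth 13, ordered by (bond distance
  ascending, type ascending, neighbor-type multiset). The multiset key
  resolves equal-distance equal-type ordering; any remaining ties
  contribute identical bytes and are harmless. One byte per type.
  Note the digest hashes the *type sequence only* (no distance
  markers): molecules whose atoms all share one type can alias — with
  hydrogens present (the expected inputs) the shells differ and, e.g.,
  toluene's ortho/para carbons separate cleanly.
* Symmetry RMSD: Hungarian assignment on squared distances within each
  digest group (squared, because RMSD minimizes summed squared
  deviation); never exceeds the naive ordered RMSD, may undershoot the
  automorphism-constrained optimum when the digest heuristic merges
  atoms no automorphism relates — accepted, as the digest is a
  documented heuristic.
* INON/EN: first index within 2 Å symmetry-RMSD of the optimized
  native pose (ligand atoms, hydrogens included; a heavy-only variant
  is exposed on the `rmsd` CLI via naive/symmetry switches); EN
  additionally within ± 1 kcal/mol. Both `inf` when nothing qualifies.

## Fixtures and what they do (and do not) show

The toy cavity is a squeezed icosahedral cage of 12 sulfur atoms
(radius 4.2 Å, y/z scaled by 0.85) around a carbon diatomic; the
anisotropy makes the planted x-aligned pose the unique well-fitting
orientation. The clash variant replaces the two on-axis vertices with
a blocking sulfur 3.1 Å behind one ligand tip and a clashing hydrogen
1.48 Å in front of the other. These parameters were fixed by
brute-force surveys: the planted pose is the interior global minimum of
the cavity; in the clash system a rigid-receptor optimization from the
native pose stays trapped ≈ 0.26 Å away at ≈ +2.6 kcal/mol with no
other minimum within 0.5 Å, while the hydrogen's ≤ 0.5 Å retreat
relieves the strain and makes the native basin the global minimum.
The toy docking cube (edge 4 Å) keeps the search inside the cage;
production defaults remain 10 Å.

Desk-scale problem sizes used throughout the tests and the acceptance
script: `d ≤ 15`, `m ≤ 5` for docking runs (10 iterations, r_max 4),
`m = 3` for exhaustive grid oracles, `n^d ≤ 3·10^5` for dense tensor
scans — chosen so every brute-force oracle is enumerable and the whole
suite runs on one core in about a minute.

What passing these fixtures does *not* show: anything quantitative
about real protein–ligand energetics. The toy force field has no
solvent, no electrostatic subtlety, and the cage has none of the
frustration of a real active site; the fixtures certify the machinery
(exact interpolation, optimizer reliability, dedup/symmetry/index
logic, the moveable-atom mechanism), not chemistry. Likewise the
diatomic ligand has no torsions — torsion handling is exercised by the
chain fixtures and geometry oracles, not by the docking runs.

## Known limitations

* Single-process execution; the design permits parallel energy
  evaluation (the oracle is stateless per index) but no MPI/threading
  is shipped.
* The reference force field's angle/torsion parameters are generic;
  ring strain and conjugation are not modeled.
* The digest heuristic can merge atoms that no graph automorphism
  relates, making the symmetry RMSD a lower bound in rare cases.
* Evaluation counts are affine, not strictly proportional, in `d`
  (cheaper boundary unfoldings) — visible when comparing very small
  dimensions.
* Macrocycle flexibility is not representable by the torsion model
  (ring bonds are never rotatable), matching standard torsion-tree
  docking practice.
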