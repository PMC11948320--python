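# Methods

## Molecular model and perception

A molecule is a typed graph: atoms (element, optional formal charge),
bonds (single/double/triple/aromatic/amide), and one or more conformer
coordinate sets. Connectivity is required. Smallest-ring membership per
atom is computed by removing each incident ring bond and measuring the
shortest alternative path; aromatic flags come from cycles within the
aromatic-bond subgraph. Topological equivalence classes are found by
iterative (Morgan-style) refinement of an initial invariant
(element, degree, formal charge, aromaticity, smallest ring size): each
round re-labels an atom by its own label plus the sorted multiset of
neighbor labels, until the partition stabilizes. The refinement is
provably never finer than the automorphism orbits, which the test suite
checks against a brute-force orbit computation on small graphs.

mol2 I/O covers the SYBYL subset needed here, including formal charges
via `@<TRIPOS>UNITY_ATOM_ATTR`. The written charge column is rounded by
the largest-remainder rule so the printed six-decimal values sum exactly
to the molecular net charge. xyz input perceives bonds with a covalent-
radius criterion, d < r_i + r_j + 0.4 Å.

## Bond-type keys and corrections

An atom-type is assigned by the first matching rule in an ordered table
(element, degree, aromaticity, ring size, required neighbors). A bond's
canonical key is the lexicographically ordered type pair plus a bond
class (single/double/triple/aromatic/amide/delocalized) and an
orientation sign recording which end carries the first type. The
`delocalized` class covers carboxylate C–O (two terminal oxygens, group
charge −1) and nitro N–O. A correction value b for key (α, β, class) is
added to the α-end atom and subtracted from the β-end atom; keys with
α = β contribute nothing. Because every correction is an antisymmetric
within-bond transfer, the molecular charge is conserved exactly, and the
whole correction step can equivalently be written q = p + A·b with an
oriented atom-by-key incidence matrix A — the package exposes both paths
and the tests require them to agree to machine precision.

## Base charges (EEM)

Base charges come from electronegativity equalization: minimizing
E(q) = Σ χ_i q_i + Σ η_i q_i² + κ Σ_{i<j} q_i q_j / r_ij subject to
Σ q_i = Q gives an (n+1)-dimensional linear system with 2η on the
diagonal, κ/r off-diagonal (κ = 14.4 V·Å/e) and a Lagrange row for the
total-charge constraint. EEM is deliberately geometry-sensitive — it
stands in for the semi-empirical Mulliken populations used by production
BCC models, which are out of scope — and the shipped χ/η table is a
labeled synthetic stand-in tuned only for numerical conditioning. The
two-site closed form q₁ = (χ₂ − χ₁ + Q(2η₂ − κ/r)) / (2η₁ + 2η₂ − 2κ/r)
serves as the analytic oracle in tests.

## Correction fitting

Given training molecules with base charges p and reference targets
(per-atom charges, or ESP values on grid points through the Coulomb
kernel with 332.0637 kcal·Å/(mol·e²)), the design matrix stacks per-
molecule incidence blocks over the union key set, and b is estimated by
minimum-norm least squares via SVD. Singular directions below the
numerical-rank tolerance define a null-space basis of unidentifiable key
combinations (e.g. two keys whose incidence columns coincide on the
training set), which is reported rather than silently resolved; optional
Tikhonov (ridge) filtering s/(s²+λ) shrinks the solution.

## Torsional conformers

Rotatable backbone dihedrals take states in {t: 180°, g+: 60°, g−: −60°}.
A symmetric chain makes state vectors equivalent under chain reversal,
mirror reflection (global sign flip of all dihedrals), and their
composition. Unique conformations are enumerated as lexicographically
minimal orbit representatives, and the count is independently verified
by Burnside's lemma: for n dihedrals the fixed-point counts are 3ⁿ
(identity), 1 (mirror), 3^⌈n/2⌉ (reversal) and 3^⌊n/2⌋ (both), giving
(27 + 1 + 9 + 3)/4 = 10 for n = 3. Geometries are built by natural-
extension-reference-frame placement along the backbone with tabulated
bond lengths and tetrahedral angles; terminal substituents are placed by
bisector/cone construction.

## Conformational charge fluctuation

Assigning charges to the same molecule in several conformations gives a
per-atom standard deviation across conformers (population STD, ddof = 0,
recorded in the report). Aggregation is by per-atom value, by mean over
each topological-equivalence class, and by molecule average (mean over
atoms), so class means weighted by class size recover the molecule
average exactly. The canonical worked example: per-class STDs 0.0246
(hydroxyl O, ×2), 0.0078 (hydroxyl H, ×2), 0.0219 (methylene H, ×4),
0.0475 (C, ×2) average to 0.0247 over the ten atoms of ethylene glycol.
Point-charge dipoles (Debye; 1 e·Å = 4.80320 D) and quadrupoles
(traceless Θ or raw second moment, centroid origin by default) support
electrostatics comparisons across conformers by per-component RMSE and
squared correlation.

## Solvation statistics

For records pairing experimental and calculated solvation free energies
(signed error = calculated − experimental): mean signed error, mean
unsigned error, RMSE, Pearson R, and the Pearlman predictive index
PI = Σ w_ij c_ij / Σ w_ij over pairs i<j with weights
w_ij = |ΔG_exp,j − ΔG_exp,i| and c_ij the sign of the product of
calculated and experimental differences (0 on calculated ties). The
suite also reports fractions within error bands, molecular-weight-binned
mean signed errors, and per-group summaries with a small-group flag.
Transfer free energy between solvents is ΔG_b − ΔG_a and converts to the
partition coefficient by logP = −ΔG_trans/(RT ln 10) with
R = 1.98720×10⁻³ kcal/(mol·K); the conversion is linear, so error
statistics convert by the same factor (1 log unit ≈ 1.364 kcal/mol at
298 K, e.g. MUE 0.63 kcal/mol ↔ 0.46 log units).

## Synthetic fixtures

All tests and demos run offline on seeded synthetic data: valence-
correct random molecular graphs grown as trees (optionally seeded with a
5/6-ring template) with hydrogens completing valences, embedded by
breadth-first internal-coordinate construction; random correction tables
bounded by a scale parameter; and conformer ensembles made by Gaussian
coordinate jitter followed by iterative bond-length restoration, so the
perturbation lives in angles and torsions. These ensembles emulate the
mechanics of conformational charge variation, not Boltzmann-weighted
physical ensembles.
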