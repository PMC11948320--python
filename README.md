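# bcckit

Bond-charge-correction (BCC) charge models for small molecules: atom and
bond-type perception, correction application and fitting, torsional
conformer enumeration, conformational charge-fluctuation analysis, and
solvation free-energy error statistics.

## The scientific problem

Fixed-charge force fields need per-atom partial charges. The accurate
route — restrained fitting to a quantum electrostatic potential (RESP) —
is expensive and, worse, *conformation-dependent*: the same molecule
charged from two conformers gets measurably different charges, which
leaks conformational noise into free-energy predictions. The BCC family
(AM1-BCC and successors) takes a cheap, conformation-robust base charge
and adds a small tabulated correction per **bond type**: each correction
moves charge from one end of a bond to the other, so total molecular
charge is conserved by construction, and topologically equivalent atoms
get identical charges.

`bcckit` implements that machinery end to end at desk scale:

- **chem model + I/O** — molecules as typed graphs with conformers;
  SYBYL mol2 (read/write, formal charges, byte-stable round-trips with a
  charge column that sums exactly to the net charge), xyz with covalent-
  radius bond perception, SDF via RDKit (optional extra).
- **typing** — ordered first-match atom-type rules; canonical oriented
  bond-type keys with a `delocalized` class for carboxylate and nitro
  groups; topological equivalence classes by iterative refinement.
- **charge engine** — electronegativity-equalization (EEM) base charges
  (a geometry-sensitive stand-in for semi-empirical populations),
  correction application per bond or as an incidence-matrix product,
  symmetrization over equivalence classes.
- **fitting** — minimum-norm least squares for correction values against
  reference charges or ESP grids, with explicit null-space reporting for
  unidentifiable key combinations and optional ridge regularization.
- **conformers** — torsional state enumeration over {trans, gauche+,
  gauche−} modulo chain-reversal and mirror symmetry (explicit orbits
  cross-checked by Burnside counting) and 3-D construction of each
  unique rotamer.
- **analysis** — per-atom/per-class/molecule-average charge STDs across
  conformers; point-charge dipoles and quadrupoles in Debye.
- **solvation stats** — MSE/MUE/RMSE, Pearson R, the Pearlman predictive
  index, error-band fractions, molecular-weight-binned signed errors,
  transfer free energies and the logP conversion.
- **fixtures** — seeded synthetic molecules, correction tables and
  jittered conformer ensembles so everything above is testable offline.

## Worked example

Ethylene glycol has three rotatable dihedrals (H–O–C–C, O–C–C–O,
C–C–O–H), each in three staggered states. Naively that is 27 rotamers,
but the molecule is symmetric under chain reversal and mirror reflection,
leaving exactly **10** unique conformations:

```pycon
>>> from bcckit.conformers import TorsionSpec, enumerate_unique_states, \
...     count_unique_states_burnside
>>> spec = TorsionSpec.full(3)
>>> len(enumerate_unique_states(spec))
10
>>> count_unique_states_burnside(spec)   # independent closed-form route
10
```

The CLI builds each one as a mol2 file and assigns symmetrized BCC
charges (output below is the literal program output):

```console
$ bcckit enumerate-conformers --in glycol.mol2 --backbone 7,3,1,2,4,8 --out-dir confs
10 unique conformers (ops: identity, mirror, reversal, reversal_mirror) -> confs

$ bcckit assign --in glycol.mol2 --out glycol_charged.mol2 --symmetrize
wrote glycol_charged.mol2 (provenance: eem+bcckit-default+sym)

$ head -10 glycol_charged.mol2
@<TRIPOS>MOLECULE
ethylene_glycol
10 9 1 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
    1 C1           1.4367       1.3482       0.0000 C.3    1 MOL   0.025248
    2 C2           2.9667       1.3482      -0.0000 C.3    1 MOL   0.025248
    3 O1           0.9600       0.0000       0.0000 O.3    1 MOL  -0.035697
    4 O2           3.4433       2.6964      -0.0000 O.3    1 MOL  -0.035697
```

Note the two carbons (and the two oxygens) carry identical charges —
symmetrization averaged over topological-equivalence classes — and the
charge column sums to exactly zero at the printed precision.

Transfer free energies convert linearly to logP; at 298 K one log unit
is RT·ln 10 ≈ 1.364 kcal/mol:

```console
$ bcckit transfer --dg-a -6.30 --dg-b -8.10
dG_trans = -1.8000 kcal/mol   logP = +1.3194
```

The same factor converts error statistics: a mean unsigned error of
0.63 kcal/mol in transfer free energy is 0.46 log units in logP.

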