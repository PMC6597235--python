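# Methods

## Scope and data flow

The package analyses *given* docking outputs; it never generates poses or
dock scores itself. Two decoupled halves:

1. **Geometry** — PDB complexes are split into protein/ligand, and
   per-residue ΔASA, non-bonded contacts and hydrogen bonds are measured.
2. **Tables** — dock-score tables drive ranking, dual-target consensus,
   ΔG→pKd conversion, drug-likeness and decoy-based enrichment.

This split lets published per-residue tables and score tables drive the
downstream arithmetic even when the original poses are unavailable.

## Accessible surface area

Shrake–Rupley with a deterministic lattice: for atom *i* with van der
Waals radius *rᵢ*, test points are placed on the sphere of radius
*rᵢ + r_probe* using a golden-angle generalized spiral; a point is buried
if it falls inside any neighbour's expanded sphere, and
ASA = (exposed fraction) · 4π(rᵢ + r_probe)².

- **Probe radius** 1.4 Å (water). **Points per atom** 960 — at this count
  the total ASA of random ≤20-atom clusters agrees with an independent
  10⁶-sample Monte-Carlo surface estimate to well within 2%, matching the
  accuracy class of the classic Fortran surface programs. A fixed spiral
  (not random sampling) makes results bit-reproducible.
- **Radii**: Chothia/Naccess-style heavy-atom values keyed by element
  (C 1.87, N 1.65, O 1.40, S 1.85, P 1.90 …); unknown elements fall back
  to 1.80 Å with a logged warning.
- **ΔASA** uses the as-docked protein conformation for both states (rigid
  assumption): free-state ASA from the protein alone, bound-state ASA with
  ligand atoms present purely as occluders. With identical point sets this
  makes ΔASA ≥ 0 structurally.
- A residue is classified as participating in binding if ΔASA exceeds
  10 Å² *strictly* — 8.9 Å² fails, which is exactly how the borderline
  valine in the reference mTOR profile is treated.

Hydrogens are dropped on reading: crystal structures and docking outputs
usually lack them, and the heavy-atom convention matches the reference
surface/contact programs. Relative accessibility and polar/apolar splits
are out of scope.

## Contacts and hydrogen bonds

Distance-window criteria on heavy atoms, configurable, with defaults taken
from the 2-D interaction-diagram tradition: non-bonded contacts at
2.9–3.9 Å; hydrogen bonds as N/O/S–N/O/S pairs ≤ 3.35 Å. No angular term
is applied — without hydrogens any donor-H-acceptor angle would be a
guess, and a pure distance rule is reproducible. A pair counted as a
hydrogen bond is excluded from the contact list, so the two counts are
disjoint (as they are in the reference tables). Detection is verified
against an exhaustive O(n²) scan on every synthetic pocket.

## Binding profiles and key residues

Profiles outer-join the contact/H-bond records with the ΔASA map on the
residue identity `Xxx-123`, ordered by residue number; a residue missing
from one side carries 0 for that quantity. Key residues are the argmax
over ΔASA and (separately) over the contact count, with all ties reported
— the two criteria need not agree, and in the PI3Kγ reference profile they
do not (Lys-890 vs Met-953). "Interacting" for cross-ligand comparisons
means ≥1 contact or hydrogen bond, so a residue can be listed as
interacting yet fail the 10 Å² surface rule.

## Combinatorial enumeration

The scaffold is a SMILES string with one `[*:1]` and one `[*:2]` marker;
fragments carry a single `[*]`. Products are assembled by dummy-atom
zipping (RDKit `molzip`), sanitized and canonicalized. Numbering is
R1-major/R2-minor — `(r1−1)·|R2| + r2` — recorded in the library metadata
because "systematic substitution" admits either order. The packaged
default configuration is *synthetic*: the study scaffold and R1 groups
exist only as drawings, so a quinoxaline-sulfonamide placeholder core and
nine aryl/heteroaryl R1 fragments ship in an editable YAML, while the five
R2 groups (-OCH₃, -OH, -NH₂, -F, -Br) are the published ones.

Descriptors: MW with implicit hydrogens; HBD = N/O atoms bearing ≥1 H;
HBA = N + O count; rotatable bonds = non-ring single bonds between
non-terminal heavy atoms, amide C–N excluded; logP by Wildman–Crippen
atomic contributions. These reproduce the parent compound's published MW
(599.67), HBD (3), rotatable bonds (10) and logP (5.76); acceptor counts
and logP from graph-signature ADMET servers will generally differ and are
not treated as reference values. Rule-of-five verdicts use strict `<`
(a MW of exactly 500 or 10 rotatable bonds fails), following the
"desired value < threshold" notation of the reference drug-likeness table
rather than the classic ≤ convention.

## Screening arithmetic

- Ranking: ascending dock score, ties by compound id (deterministic under
  row permutation).
- Consensus: intersection of per-target top-k (k = 20 default), ordered by
  mean rank across targets; k larger than the library clamps with a
  warning.
- pKd = −ΔG/(ln10·R·T) with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T = 298 K
  (ln10·R·T = 1.36381 kcal/mol), rounded to 2 decimals. The tabulated
  reference ΔG/pKd pairs reproduce to ±0.01–0.015 (the source's own
  rounding).
- EF = (hits/n_sample)/(H/N) with n_sample = ⌊fraction·N⌋ (20% of 606 →
  121). With 6 actives in 606 the perfect-separation EF at 20% is
  606/121 ≈ 5.01, and the random-ranking expectation is exactly 1. The
  reference study quotes EF values (6.67, 16.67) and a "maximum of 20" at
  this level that the printed formula cannot produce with these counts;
  the implementation follows the formula and does not attempt to
  reproduce those numbers.

## Synthetic data

`make_pocket_complex` plants features with exact geometry: residues are
minimal Gly/Ala-like heavy-atom templates spaced 15 Å apart (far beyond
any cutoff); contact atoms (carbons) are placed on outward rays from the
Cβ at the requested distance, on a 15° cone when several share a residue;
hydrogen-bond partners extend the C=O or Cα–N axis so the only protein
atom in range is the intended donor/acceptor; burial caps sit at 5 Å —
inside occlusion range of the expanded spheres but outside contact range.
Per-residue translational jitter (seeded, ±0.3 Å) varies geometry between
seeds without perturbing planted distances. The generator re-detects its
own ledger with the exhaustive scan and refuses to return a pocket with
accidental extras, so ledger-vs-detection tests are exact, not
approximate. Rotamer realism is deliberately absent — the generator
exercises the measurement code, not protein physics, so passing tests
certify the arithmetic and geometry predicates, not performance on real
pockets.

`make_score_table` draws decoy scores from Normal(μ, σ) and active scores
from Normal(μ + δ, σ) with μ = −35, σ = 3 (a typical grid-score scale)
and δ = −6 by default; only rank order matters to EF, so the Gaussian
choice is immaterial. The canonical screen size follows the reference
protocol: 6 actives × 100 decoys each = 606 compounds.

`synthetic_s1_table` reconstructs the 45-compound × 2-target score table
from its published anchors: the six selected compounds at their published
ranks/scores per target, fillers interpolated monotonically between
anchors, and filler top-20 membership drawn from opposite ends of the
compound list for the two targets so the top-20 intersection is exactly
the published six. It is a stand-in for rank arithmetic, not real docking
data, and is labelled synthetic wherever it appears.

## Numerical and edge-case choices

- Altloc resolution: highest occupancy, tie → altloc 'A'. Waters and
  non-ligand heteroatoms excluded by default, flag-re-includable.
- Zero-atom structures, empty ligands, selectors matching ≠1 residue,
  empty profiles, zero-active enrichment: explicit errors (or empty
  results where the spec of the operation makes that the honest answer —
  an empty ligand yields an empty contact list).
- Reported ΔASA and H-bond lengths round to 2 decimals in outputs; full
  precision is kept internally.
- All generators take an integer seed and are deterministic across runs;
  the pipeline writes byte-identical reports under a fixed config.

## Problem sizes in the shipped tests

Property tests use pockets of ≤6 residues (≤30 protein atoms), Monte-Carlo
cross-checks use 10⁵–10⁶ samples on ≤20-atom clusters, enrichment
simulations use 10²–10⁴ permutations of the 606-compound screen, and the
library tests enumerate the full 45-compound configuration. These sizes
were chosen so the whole suite exercises every code path in seconds while
keeping sampling error far below the asserted tolerances.

## Known limitations

- No angular hydrogen-bond criterion and no π-stacking/aromatic detection.
- ΔASA assumes the rigid as-docked conformation; induced fit is invisible.
- The placeholder scaffold/R1 fragments are not the study's real
  structures; descriptor values for enumerated compounds are therefore
  illustrative until a user supplies the real config.
- mmCIF, assemblies and structure preparation (protonation, minimization)
  are out of scope.
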