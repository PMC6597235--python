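# dualprofiler

Post-docking analysis of protein–ligand complexes for **dual-target
inhibitor discovery** — the workflow used to dissect how an inhibitor such
as the PI3Kγ/mTOR dual inhibitor XL765 engages two kinase pockets at once,
and to pick better candidates from a scaffold-derived combinatorial
library.

It is aimed at computational chemists who already have docking poses and
score tables (from DOCK, Vina, Glide, …) and want the downstream analysis:
who binds, how tightly, and which library members to take forward.

## What it computes

**Per-residue binding profiles.** For a docked complex split into protein
and ligand, each pocket residue gets:

- its loss of solvent-accessible surface area on binding,
  ΔASA = ASA(free) − ASA(complex), from a Shrake–Rupley calculation
  (probe 1.4 Å, 960 deterministic spiral-lattice test points per atom,
  Chothia-style heavy-atom radii). A residue "takes part in binding" if
  ΔASA > 10 Å²;
- its non-bonded contact count (heavy-atom pairs at 2.9–3.9 Å) and
  hydrogen bonds (N/O/S donor–acceptor pairs ≤ 3.35 Å, distance-only since
  hydrogens are absent);
- *key residues* are the argmax over ΔASA and over contact count
  (ties reported).

**Combinatorial libraries.** A scaffold with `[*:1]`/`[*:2]` attachment
markers crossed with R1 × R2 substituent sets gives |R1|·|R2| products,
numbered systematically (R1-major), with rule-of-five descriptors
(MW, H-bond donors/acceptors, rotatable bonds, Wildman–Crippen logP) and
strict `<` verdicts against 500/5/10/10/5.

**Dual-target screening.** Compounds are ranked per target by dock score
(more negative = better); the consensus selection is the intersection of
each target's top-k (default k = 20), ordered by mean rank. Binding free
energies convert to dissociation constants via

```
pKd = −ΔG / (ln 10 · R · T),   R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹, T = 298 K
```

**Enrichment evaluation.** Against a decoy background (100 decoys per
active in the reference protocol), the enrichment factor at a fraction *f*
of a ranked database of *N* compounds with *H* actives is

```
EF = (Hits_sample / N_sample) / (H / N),   N_sample = ⌊f·N⌋
```

with the cumulative actives-found curve alongside. A random ranking gives
EF = 1 in expectation.

## Worked example

```python
from dualprofiler.fixtures import load_fixtures
from dualprofiler.screening import rank_compounds, consensus_topk, energy_to_pkd

fx = load_fixtures()
rankings = {t: rank_compounds(fx.s1, t) for t in ["PI3Kgamma", "mTOR"]}
print("dual-target consensus (top-20):", consensus_topk(rankings, k=20).intersection)
for dg in (-9.14, -9.98):
    print(f"ΔG = {dg:6.2f} kcal/mol  →  pKd = {energy_to_pkd(dg):.2f}")
```

prints

```
dual-target consensus (top-20): [28, 18, 38, 9, 10, 19]
ΔG =  -9.14 kcal/mol  →  pKd = 6.70
ΔG =  -9.98 kcal/mol  →  pKd = 7.32
```

The six compound numbers are the library members scoring in the top 20
against *both* kinases — the proposed dual inhibitors — and the pKd values
are the dissociation constants implied by their best binding energies.
On a synthetic screen with a planted active-vs-decoy score shift the
enrichment factor approaches its perfect-separation value:

```
EF@20% = 5.01  (6/121 actives in subset, 6/606 overall)
```

The full pipeline (profiles → library → screening → enrichment) runs with

```
dualprofiler run --seed 1 --out reports/
```

and writes TSV/JSON reports (per-residue profiles, key residues, the
45-compound library with verdicts, the consensus list, enrichment curves);
`dualprofiler synth pocket|screen` emits seeded synthetic inputs, and
`split / asa / interactions / profile / library / screen / enrich` expose
each stage on its own.

## Notes

The packaged reference tables (`dualprofiler/data/`) carry the per-residue
profiles, rule-of-five values and residue memberships of the original
XL765 study; the 45-compound dock-score table is a *synthetic*
reconstruction anchored to the six published rank/score pairs per target
(see `dualprofiler.fixtures.synthetic_s1_table`). Docking itself, X-Score
rescoring and ADMET graph models are out of scope: poses and scores are
inputs here.
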