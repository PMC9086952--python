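# aggtol

Comparative analysis of **protein aggregation propensity** and **mutation
tolerance** between two species' orthologous proteomes.

Long-lived species are thought to maintain protein homeostasis in part
through the intrinsic architecture of their proteomes: proteins that are
less prone to form β-aggregates, and proteins that can absorb random
coding mutations without becoming more aggregation-prone. `aggtol`
implements the computational side of that comparison for any pair of
species: per-residue aggregation scores aggregated to whole-protein and
per-domain values, cross-species z-score classification, exhaustive
single-nucleotide in-silico mutagenesis, alignment-mapped mutational
profiles, and local annotation-term enrichment — plus a synthetic
ortholog-pair generator with planted ground truth so every stage is
testable without downloads.

## The quantities

Given per-residue aggregation scores (from any predictor; a windowed
Kyte–Doolittle surrogate ships with the package, and Tango-style score
files are read directly):

* **Agg_P** = Σ per-residue score / protein length, and **Agg_D** the same
  over an annotated domain interval.
* **ΔAgg** = Agg(species A) − Agg(species B) per ortholog pair, z-scored
  over the analyzed set; |z| > 2 flags a pair as significantly
  higher/lower in species A.
* **Mutational Agg_P** = Agg_P(mutant) − Agg_P(wild type) for every
  distinct protein produced by the 3L single-nucleotide substitutions of
  an L-nucleotide CDS (after removing synonymous events, start-codon
  losses, and length-changing events).
* **Strict mutation tolerance** = fraction of distinct mutants with
  Mutational Agg_P = 0; **lenient** additionally counts decreases;
  mutants below −1 / above +1 are **beneficial** / **detrimental**.
* **Fold enrichment** = (subset hit rate)/(background hit rate) per
  annotation term, with two-sided Fisher exact p-values and
  Benjamini–Hochberg FDR per aspect.

See `docs/methods.md` for the full model, parameter defaults, and
numerical conventions.

## Worked example

The shortest interesting substrate is the CDS `ATGAAATAA` (protein `MK`):

```python
from aggtol import CodingRecord, summarize_protein

rec = CodingRecord.from_cds("demo", "ATGAAATAA")
s = summarize_protein(rec)          # default hydropathy surrogate
print(sorted(s.mutational_agg))     # distinct qualifying mutants
print(s.mutational_agg["MI"])       # change in Agg_P for the M->I mutant
print(round(s.strict_tolerance, 6))
```

prints

```
['ME', 'MI', 'MN', 'MQ', 'MR', 'MT']
48.0
0.833333
```

Of the 27 possible single-nucleotide events, 9 change the start codon,
8 change the translated length, and 3 are synonymous; the remaining 7
events yield 6 distinct mutant proteins. Only `MI` (lysine → isoleucine)
pushes the two-residue window mean over the surrogate's activation
threshold, raising Agg_P by +48.0 — a detrimental mutation — so the
protein tolerates 5 of its 6 distinct mutants exactly (strict tolerance
0.833333), and no mutation lowers aggregation (beneficial share 0).

## Running the pipeline

```
aggtol simulate --out data/ --n-pairs 500 --n-differential 25 --seed 1
aggtol run-all  --data data/ --out results/
```

`run-all` executes qc → score → compare → mutate → profile → enrich,
writing one TSV per stage (QC report, protein/domain scores and deltas,
tolerance statistics, aligned profiles with hotspot calls, enrichment
tables), a machine-readable `summary.json` of per-stage counts, and a
`manifest.json` with config snapshot and input/output digests. Repeated
runs on identical inputs are byte-identical. Every stage is also
available as a library function and as its own subcommand; thresholds
(60% similarity, 20% gaps, 10,000-residue cap, ±2 z, ±1 hotspot, 5-protein
enrichment minimum) are config keys.

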