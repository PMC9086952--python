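# Methods

`aggtol` compares two species' orthologous proteomes on two intrinsic
sequence properties: **aggregation propensity** (the tendency of local
sequence windows to form β-aggregates) and **mutation tolerance** (the
ability of a protein to absorb single-nucleotide substitutions without
changing that propensity). This note records the models, the parameters
that matter, the numerical conventions, and what the synthetic benchmark
does and does not show.

## Aggregation scoring

The pipeline is predictor-agnostic: every downstream formula consumes a
per-residue score vector in [0, 100] and nothing else. Scores can come
from external per-residue score files (a simple TSV dialect, or a
configurable whitespace "tango" dialect for output of Tango-style
predictors), or from the built-in surrogate predictor.

The surrogate is a deliberately simple, fully specified windowed-hydropathy
scorer, so that the whole pipeline is testable and reproducible without a
closed-source predictor. For residue *i* of a protein of length *L*, with
window width *w* (odd; default 5) truncated at the termini,

    raw_i   = mean of scale values over [max(1, i-w//2), min(L, i+w//2)]
    score_i = 0                                    if raw_i <= θ
            = 100 · min(1, (raw_i - θ)/(s_max - θ)) otherwise

with the Kyte–Doolittle hydropathy scale, activation threshold θ = 2.0 and
s_max = 4.5 (the scale maximum, reached by poly-Ile). The surrogate is
deterministic and monotone: replacing a residue by one of strictly higher
scale value never decreases any score. It is *not* a reimplementation of
any statistical-mechanics aggregation model; when real predictor output is
available it should be supplied through score files
(`predictor.kind = file`), and all results then depend only on those
vectors.

Aggregate scores are length-normalised sums:

    Agg_P = Σ_i score_i / L                    (whole protein)
    Agg_D = Σ_{i∈domain} score_i / |domain|    (per annotated domain)

Domain intervals are Pfam-style 1-based inclusive coordinates on the focal
species; the partner species' intervals are obtained by projecting the
coordinates through the pair's global alignment (a boundary falling in a
gap snaps to the nearest aligned residue inside the domain; a domain whose
whole interval is deleted in the partner is dropped and reported). This
projection replaces a reciprocal-best-hit domain transfer: the pipeline
already holds the pairwise alignment, and projection uses exactly the
homology information that alignment encodes.

## Ortholog QC

Candidate pairs (consumed as a precomputed table; no ortholog detection is
performed) are aligned with Smith–Waterman local alignment under BLOSUM62,
gap open 14, gap extension 4 — the defaults of the EMBOSS Matcher tool —
where a gap of length k costs 14 + 4(k−1). Percent similarity counts
matrix-positive aligned columns (not identities) over all alignment
columns; percent gaps counts gap columns. A pair fails QC when similarity
is strictly below 60%, gaps strictly above 20%, either protein appears on
the exclusion list (e.g. transmembrane proteins, supplied externally), or
either protein exceeds 10,000 residues. Exactly-at-threshold pairs pass.
Each pair lands in exactly one partition, with filters applied in the
order similarity, gaps, exclusion, length.

## Saturation mutagenesis and tolerance scores

Every nucleotide of a CDS of length L is substituted to the three other
bases: 3L events, terminal stop codon included, self-substitutions
excluded. Because one event changes exactly one codon, classification
splices the affected residue into the wild-type protein rather than
re-translating the CDS; the test suite verifies this against a naive
full-retranslation oracle. Events are classified in order:

1. **synonymous** — mutant protein identical to wild type (including
   stop→stop events at the terminal codon);
2. **start_loss** — mutant protein empty or not beginning with M;
3. **length_change** — premature stop or stop-loss (translated length
   differs from wild type);
4. **qualifying** — everything else; the mutant protein enters a
   deduplicated set.

For each distinct qualifying mutant,

    mutational Agg_P = Agg_P(mutant) − Agg_P(wild type)

computed on 6-decimal-rounded scores, so that the "no change" category is
a well-defined equality across platforms. Tolerance statistics use the
number of distinct mutant proteins as denominator by default (an
event-weighted variant is available via `mutagenesis.denominator=events`,
since saturation counts can reasonably be per-event or per-sequence):

    strict tolerance   = #(mutational Agg_P = 0)  / n
    lenient tolerance  = #(mutational Agg_P ≤ 0)  / n
    beneficial share   = #(mutational Agg_P < −1) / n
    detrimental share  = #(mutational Agg_P > +1) / n

with strict ≤ lenient and strict + beneficial ≤ lenient by construction.
Per-site landscapes keep one entry per qualifying *event* (not per
distinct protein), attached to the mutated codon's residue position.

## Cross-species comparison

Per-unit deltas (focal species minus partner) of Agg_P, Agg_D, and strict
tolerance are standardized into z-scores with the sample (n−1) standard
deviation over the full analyzed set at each level; protein-level and
domain-level standardizations are independent, and domain z-scores pool
all domains rather than normalising within proteins. Units with z > 2 are
classed "higher" in the focal species, z < −2 "lower", otherwise
"similar". A reporting helper counts higher/lower units per level and the
union of distinct proteins significant at either level. The classical
tests exposed alongside (Pearson correlation, two-sample KS, Student's
pooled-variance t) are validated wrappers over scipy; degenerate inputs
(zero variance, empty samples) raise instead of returning NaN.

## Profiles and hotspots

For selected pairs, per-residue scores and per-site mutational landscapes
from both species are joined column-wise on a Needleman–Wunsch global
alignment (same scoring as QC; an externally computed aligned FASTA is
accepted verbatim). Gap columns export missing values, never zero. A
column is a detrimental hotspot for a species when at least one of its
site mutations has mutational Agg_P strictly above +1, beneficial when
strictly below −1; counts per column are reported, and because per-residue
summarisation choices vary, the long-format export also carries per-site
min/max. Maximal gap runs are reported per species in alignment
coordinates; no attempt is made to decide whether a gap is an insertion or
a deletion against outgroup databases.

## Enrichment

Annotation-term enrichment is fully local, on a user-supplied
protein→term table with BP/MF/CC aspects (no ontology-graph propagation:
annotations are used as given, which can make counts differ from services
that propagate ancestors internally). Per term, a two-sided Fisher exact
test on the 2×2 subset/background table; fold enrichment
FE = (k/n)/(K/N) with log2 FE reported; Benjamini–Hochberg FDR within
each aspect. Terms with fewer than 5 subset hits are excluded *before*
testing (the conservative reading of a display rule; a flag restores
display-only filtering). A per-term chi-square (no continuity correction)
compares how two protein groups distribute over terms, falling back to
Fisher's exact test, flagged, when an expected cell is zero.

## Synthetic data generator

The generator produces the inputs the pipeline consumes, with ground
truth. Per pair: an ancestor protein (leading M plus residues drawn from
uniform amino-acid frequencies) is back-translated with uniform synonymous
codon choice plus one stop codon; each species' CDS then receives
independent nonsynonymous codon substitutions at the configured per-codon
rate (start and stop codons untouched; stop-creating draws rejected, so
every synthetic CDS stays valid). Differential pairs get a contiguous
poly-isoleucine segment inserted at a random interior codon boundary in
exactly one species (insertion mirrors the biologically interesting case
of a species-specific indel inside an aggregation peak; an in-place
replacement mode exists as an option). Domains are 1–3 random intervals
per focal protein; annotation terms are assigned at an 8% background rate
except the planted term, enriched 5-fold among differential proteins.
One master seed drives everything; each pair uses a substream keyed by a
stable hash of its pair id, so growing the dataset never perturbs
existing pairs.

Default study conditions: 500 pairs of 80–150 residues, 2% nonsynonymous
rate, 25 differential pairs with an 8-residue segment, 50 chaperone-client
pairs, 20 annotation terms. Protein lengths are deliberately shorter than
typical real proteomes so that full saturation mutagenesis of every pair
is cheap; scores and tolerances are length-normalised, so the analysis
logic is unchanged. What the benchmark shows: the pipeline recovers
planted differential pairs and planted enriched terms at these effect
sizes, and reproduces the expected negative correlation between Agg_P and
strict tolerance (a partly mechanical consequence of both being driven by
the density of score-active windows). What it does not show: performance
on real divergence patterns, real amino-acid composition, real domain
architectures, or real annotation structure — none of which the generator
attempts to emulate, and all of which also depend on the external
predictor actually used.

## Numerical conventions and degenerate inputs

* All derived aggregate scores are rounded to 6 decimals before equality
  comparisons; per-residue scores are carried at full precision.
* File coordinates are 1-based inclusive; conversion to 0-based half-open
  happens exactly at the reader/writer layer.
* Genetic code: NCBI table 1 by default, configurable.
* A CDS with a premature stop is rejected at load time; a terminal stop is
  allowed and recorded, and the protein string never contains it.
* Alignment tie-breaks follow the aligner's deterministic first-alignment
  choice; alignment *scores* are tie-break invariant and are what the
  oracle tests compare.
* Standardization requires at least 3 units and nonzero standard
  deviation; the t-test rejects zero pooled variance; Pearson rejects
  zero-variance inputs.
* Score files round-trip bitwise (full-precision float repr on write,
  round-trip float parsing on read).

## Known limitations

* The surrogate predictor is a stand-in with a different functional form
  from statistical-mechanics aggregation predictors; absolute score
  levels are not comparable across predictors, only pipeline behaviour.
* Domain projection assumes the pairwise alignment is trustworthy;
  misalignment propagates into Agg_D deltas.
* The enrichment module does not propagate annotations up an ontology
  graph.
* The pipeline holds all pair records and profiles in memory; it targets
  proteome-scale runs on a workstation, not metagenome-scale inputs.
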