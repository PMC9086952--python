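"""Exhaustive single-nucleotide in-silico mutagenesis and tolerance scores.

Every nucleotide of a CDS is substituted to each of the three other bases
(3L events for a CDS of length L, terminal stop codon included).  Events are
classified as synonymous, start-loss (the mutant protein no longer begins
with methionine), or length-change (premature stop or stop-loss); the rest
contribute their mutant protein to a deduplicated set.  Per-mutant changes
in whole-protein aggregation score (mutational Agg_P = Agg_P(MT) −
Agg_P(WT), on 6-decimal-rounded scores) yield:

* strict mutation tolerance — fraction of mutants with mutational Agg_P = 0;
* lenient mutation tolerance — fraction with mutational Agg_P <= 0;
* beneficial proportion — fraction with mutational Agg_P < −1 (strict
  inequality), and symmetrically detrimental for > +1.

Because a single-nucleotide event alters exactly one codon, classification
splices one residue into the wild-type protein instead of re-translating the
whole CDS; the test suite checks this against a naive full-retranslation
oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation import AggregationProfile, SurrogatePredictor, agg_p
from .io import STOP_SYMBOL, CodingRecord, codon_map, round6
from .stats import classify_z, zscores

BASES = "ACGT"

SYNONYMOUS = "synonymous"
START_LOSS = "start_loss"
LENGTH_CHANGE = "length_change"
QUALIFYING = "qualifying"

EXCLUSION_REASONS = (SYNONYMOUS, START_LOSS, LENGTH_CHANGE)


@dataclass(frozen=True)
class MutationEvent:
    """One single-nucleotide substitution event on the CDS."""

    nt_position: int  # 1-based position in the CDS
    ref_base: str
    alt_base: str
    codon_index: int  # 0-based codon index
    outcome: str  # synonymous | start_loss | length_change | qualifying
    mutant_protein: str | None  # set only for qualifying events


@dataclass(frozen=True)
class MutantSet:
    wt: CodingRecord
    events: tuple
    distinct_mutants: frozenset
    exclusion_counts: dict

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_qualifying_events(self) -> int:
        return self.n_events - sum(self.exclusion_counts.values())


def enumerate_mutants(wt: CodingRecord, max_len: int = 10_000) -> MutantSet:
    """Enumerate all 3L single-nucleotide mutants of a coding record.

    Self-substitutions are excluded.  Events that keep the protein identical
    are synonymous; a mutant protein that is empty or does not start with M
    is a start-loss; premature stops and stop-loss events (which change the
    translated length) are length-changes.  Remaining events contribute
    their mutant protein, deduplicated, to ``distinct_mutants``.
    """
    if wt.length_aa > max_len:
        raise ValueError(
            f"{wt.id}: protein length {wt.length_aa} exceeds cap {max_len}"
        )
    mapping = codon_map(wt.table)
    cds, protein = wt.cds, wt.protein
    n_codons = len(cds) // 3
    events: list[MutationEvent] = []
    counts = {SYNONYMOUS: 0, START_LOSS: 0, LENGTH_CHANGE: 0}
    distinct: dict[str, str] = {}

    for c in range(n_codons):
        codon = cds[3 * c : 3 * c + 3]
        is_stop_codon = c == n_codons - 1 and wt.has_terminal_stop
        wt_aa = None if is_stop_codon else protein[c]
        for j in range(3):
            ref = codon[j]
            for alt in BASES:
                if alt == ref:
                    continue
                new_codon = codon[:j] + alt + codon[j + 1 :]
                new_aa = mapping[new_codon]
                mutant: str | None = None
                if is_stop_codon:
                    outcome = SYNONYMOUS if new_aa == STOP_SYMBOL else LENGTH_CHANGE
                elif new_aa == wt_aa:
                    outcome = SYNONYMOUS
                else:
                    prot = (
                        protein[:c]
                        if new_aa == STOP_SYMBOL
                        else protein[:c] + new_aa + protein[c + 1 :]
                    )
                    if not prot or prot[0] != "M":
                        outcome = START_LOSS
                    elif len(prot) != wt.length_aa:
                        outcome = LENGTH_CHANGE
                    else:
                        outcome = QUALIFYING
                        # share one string object across duplicate events
                        mutant = distinct.setdefault(prot, prot)
                if outcome != QUALIFYING:
                    counts[outcome] += 1
                events.append(
                    MutationEvent(3 * c + j + 1, ref, alt, c, outcome, mutant)
                )
    return MutantSet(
        wt=wt,
        events=tuple(events),
        distinct_mutants=frozenset(distinct),
        exclusion_counts=counts,
    )


@dataclass(frozen=True)
class MutagenesisSummary:
    """Per-protein mutation-tolerance statistics and per-site landscapes."""

    protein_id: str
    wt_agg_p: float
    mutational_agg: dict  # distinct mutant protein -> mutational Agg_P
    strict_tolerance: float
    lenient_tolerance: float
    beneficial_proportion: float
    detrimental_proportion: float
    n_total: int
    per_site: dict  # residue position (1-based) -> list of (mutant, mutational Agg_P)


def _profile_scores(predictor, protein: str) -> np.ndarray:
    out = predictor(protein)
    if isinstance(out, AggregationProfile):
        return np.asarray(out.scores, dtype=float)
    return np.asarray(out, dtype=float)


def mutational_agg(
    mutants: MutantSet,
    predictor,
    denominator: str = "distinct",
) -> MutagenesisSummary:
    """Score every distinct mutant and derive the tolerance statistics.

    ``predictor`` is any deterministic callable mapping a protein string to
    per-residue scores in [0, 100].  With ``denominator='distinct'`` (the
    default) the tolerance ratios are taken over distinct mutant proteins;
    ``'events'`` weights each mutant by the number of substitution events
    producing it.
    """
    if denominator not in {"distinct", "events"}:
        raise ValueError(f"denominator must be 'distinct' or 'events', got {denominator!r}")
    wt = mutants.wt
    wt_score = round6(float(np.mean(_profile_scores(predictor, wt.protein))))

    deltas: dict[str, float] = {}
    for prot in mutants.distinct_mutants:
        mt_score = round6(float(np.mean(_profile_scores(predictor, prot))))
        if len(prot) != wt.length_aa:
            raise RuntimeError(
                f"{wt.id}: length-changing mutant slipped past filtering"
            )
        deltas[prot] = round6(mt_score - wt_score)

    per_site: dict[int, list] = {}
    event_weights: dict[str, int] = {}
    for ev in mutants.events:
        if ev.outcome != QUALIFYING:
            continue
        per_site.setdefault(ev.codon_index + 1, []).append(
            (ev.mutant_protein, deltas[ev.mutant_protein])
        )
        event_weights[ev.mutant_protein] = event_weights.get(ev.mutant_protein, 0) + 1

    if denominator == "distinct":
        weighted = [(d, 1) for d in deltas.values()]
    else:
        weighted = [(deltas[p], w) for p, w in event_weights.items()]
    n_total = sum(w for _, w in weighted)

    if n_total == 0:
        strict = lenient = beneficial = detrimental = 0.0
    else:
        strict = sum(w for d, w in weighted if d == 0.0) / n_total
        lenient = sum(w for d, w in weighted if d <= 0.0) / n_total
        beneficial = sum(w for d, w in weighted if d < -1.0) / n_total
        detrimental = sum(w for d, w in weighted if d > 1.0) / n_total

    return MutagenesisSummary(
        protein_id=wt.id,
        wt_agg_p=wt_score,
        mutational_agg=deltas,
        strict_tolerance=strict,
        lenient_tolerance=lenient,
        beneficial_proportion=beneficial,
        detrimental_proportion=detrimental,
        n_total=n_total,
        per_site=per_site,
    )


def summarize_protein(
    record: CodingRecord,
    predictor=None,
    denominator: str = "distinct",
    max_len: int = 10_000,
) -> MutagenesisSummary:
    """enumerate_mutants + mutational_agg in one call (surrogate by default)."""
    predictor = predictor or SurrogatePredictor()
    return mutational_agg(enumerate_mutants(record, max_len), predictor, denominator)


@dataclass(frozen=True)
class MutTolDelta:
    """Cross-species difference in strict mutation tolerance for one pair."""

    pair_id: str
    strict_a: float
    strict_b: float
    delta: float
    z: float
    cls: str  # higher | lower | similar


def muttol_delta(
    pair_ids,
    summaries_a,
    summaries_b,
    z_threshold: float = 2.0,
) -> list[MutTolDelta]:
    """Delta of strict mutation tolerance (species A − species B), z-scored
    over the analyzed pair set with the sample standard deviation; |z| > 2
    flags a pair as higher/lower in species A."""
    pair_ids = list(pair_ids)
    if not (len(pair_ids) == len(summaries_a) == len(summaries_b)):
        raise ValueError("pair ids and summaries must have equal lengths")
    if len(pair_ids) < 3:
        raise ValueError("need at least 3 pairs to standardize deltas")
    deltas = [
        round6(sa.strict_tolerance - sb.strict_tolerance)
        for sa, sb in zip(summaries_a, summaries_b)
    ]
    z = zscores(deltas)
    return [
        MutTolDelta(
            pair_id=pid,
            strict_a=sa.strict_tolerance,
            strict_b=sb.strict_tolerance,
            delta=d,
            z=round6(zi),
            cls=classify_z(zi, z_threshold),
        )
        for pid, sa, sb, d, zi in zip(pair_ids, summaries_a, summaries_b, deltas, z)
    ]
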