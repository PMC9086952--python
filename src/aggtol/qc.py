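"""Pairwise alignment of ortholog candidates and inclusion filtering.

Candidate pairs are locally aligned (Smith–Waterman, BLOSUM62, gap open 14 /
extend 4 — the defaults of the EMBOSS Matcher tool) and filtered on percent
similarity, percent gaps, an exclusion list (e.g. transmembrane proteins),
and a protein-length cap.  Similarity counts matrix-positive aligned
columns, not identities.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Align import PairwiseAligner, substitution_matrices

from .io import CodingRecord, round6

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 14.0
DEFAULT_GAP_EXTEND = 4.0

MIN_SIMILARITY = 60.0
MAX_GAPS = 20.0
MAX_PROTEIN_LENGTH = 10_000


@dataclass(frozen=True)
class AlignmentScoring:
    matrix_name: str = DEFAULT_MATRIX
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND


def make_aligner(mode: str, scoring: AlignmentScoring | None = None) -> PairwiseAligner:
    """Build a deterministic affine-gap aligner (a gap of length k costs
    open + (k-1) * extend)."""
    scoring = scoring or AlignmentScoring()
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix_name)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


@dataclass(frozen=True)
class PairwiseAlignmentResult:
    """One pairwise alignment with its column-level QC metrics.

    ``similarity_pct`` is the percentage of alignment columns whose residue
    pair scores positively under the substitution matrix; ``gaps_pct`` the
    percentage of columns containing a gap.
    """

    gapped_a: str
    gapped_b: str
    score: float
    similarity_pct: float
    gaps_pct: float

    @property
    def n_columns(self) -> int:
        return len(self.gapped_a)


def _column_metrics(gapped_a: str, gapped_b: str, matrix) -> tuple[float, float]:
    n_cols = len(gapped_a)
    if n_cols == 0:
        return 0.0, 0.0
    similar = gaps = 0
    for ca, cb in zip(gapped_a, gapped_b):
        if ca == "-" or cb == "-":
            gaps += 1
        elif matrix[ca, cb] > 0:
            similar += 1
    return round6(100.0 * similar / n_cols), round6(100.0 * gaps / n_cols)


def _align(a: str, b: str, mode: str, scoring: AlignmentScoring | None) -> PairwiseAlignmentResult:
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    scoring = scoring or AlignmentScoring()
    aligner = make_aligner(mode, scoring)
    aln = aligner.align(a, b)[0]
    gapped_a, gapped_b = str(aln[0]), str(aln[1])
    sim, gaps = _column_metrics(gapped_a, gapped_b, aligner.substitution_matrix)
    return PairwiseAlignmentResult(
        gapped_a=gapped_a,
        gapped_b=gapped_b,
        score=float(aln.score),
        similarity_pct=sim,
        gaps_pct=gaps,
    )


def local_align(a: str, b: str, scoring: AlignmentScoring | None = None) -> PairwiseAlignmentResult:
    """Optimal Smith–Waterman local alignment; rows span the aligned region only."""
    return _align(a, b, "local", scoring)


@dataclass(frozen=True)
class OrthologPair:
    """Two species' coding records with alignment-derived QC metrics."""

    pair_id: str
    record_a: CodingRecord
    record_b: CodingRecord
    alignment: PairwiseAlignmentResult
    is_chaperone_client: bool = False
    status: str = "pass"

    @property
    def similarity_pct(self) -> float:
        return self.alignment.similarity_pct

    @property
    def gaps_pct(self) -> float:
        return self.alignment.gaps_pct


def build_pair(
    pair_id: str,
    record_a: CodingRecord,
    record_b: CodingRecord,
    is_chaperone_client: bool = False,
    scoring: AlignmentScoring | None = None,
) -> OrthologPair:
    aln = local_align(record_a.protein, record_b.protein, scoring)
    return OrthologPair(pair_id, record_a, record_b, aln, is_chaperone_client)


@dataclass(frozen=True)
class FilterResult:
    passed: tuple
    failed: dict  # status -> tuple of OrthologPair
    counts: dict  # status -> int

    def all_pairs(self) -> list:
        out = list(self.passed)
        for pairs in self.failed.values():
            out.extend(pairs)
        return out


FAIL_STATUSES = ("fail_similarity", "fail_gaps", "fail_excluded", "fail_length")


def filter_pairs(
    pairs,
    exclusions: set[str] | None = None,
    min_similarity: float = MIN_SIMILARITY,
    max_gaps: float = MAX_GAPS,
    max_len: int = MAX_PROTEIN_LENGTH,
) -> FilterResult:
    """Partition ortholog pairs by the inclusion filters.

    Failure thresholds are strict inequalities: similarity strictly below
    ``min_similarity`` or gaps strictly above ``max_gaps`` fail, so a pair
    sitting exactly on a threshold passes.  Each pair lands in exactly one
    partition; when several filters would fire, the first in the order
    similarity, gaps, exclusion, length wins.
    """
    exclusions = exclusions or set()
    partitions: dict[str, list] = {status: [] for status in FAIL_STATUSES}
    passed: list = []
    for pair in pairs:
        if pair.similarity_pct < min_similarity:
            status = "fail_similarity"
        elif pair.gaps_pct > max_gaps:
            status = "fail_gaps"
        elif pair.record_a.id in exclusions or pair.record_b.id in exclusions:
            status = "fail_excluded"
        elif pair.record_a.length_aa > max_len or pair.record_b.length_aa > max_len:
            status = "fail_length"
        else:
            status = "pass"
        pair = replace(pair, status=status)
        if status == "pass":
            passed.append(pair)
        else:
            partitions[status].append(pair)
    counts = {"pass": len(passed)}
    counts.update({status: len(partitions[status]) for status in FAIL_STATUSES})
    return FilterResult(
        passed=tuple(passed),
        failed={status: tuple(v) for status, v in partitions.items()},
        counts=counts,
    )


def scan_descriptions_for_keyword(records, keyword: str = "transmembrane") -> set[str]:
    """Convenience: ids whose FASTA description contains ``keyword`` (case-
    insensitive).  Only ever appends to a caller-supplied exclusion list."""
    keyword = keyword.lower()
    return {r.id for r in records if keyword in getattr(r, "description", "").lower()}
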