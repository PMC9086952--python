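"""Alignment-mapped aggregation and mutational profiles for ortholog pairs.

Per-residue aggregation scores and per-site mutational landscapes from both
species are joined column-wise on a global pairwise alignment.  Columns
where one species carries a gap export missing values for that species
(never zero), which is what lets a plotting layer draw the dashed-line
convention for indels.  Hotspots are columns holding at least one site
mutation with mutational Agg_P strictly above +1 (detrimental) or strictly
below −1 (beneficial).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .aggregation import AggregationProfile
from .io import FormatError, read_fasta, round6
from .qc import AlignmentScoring, PairwiseAlignmentResult, _align

DETRIMENTAL_THRESHOLD = 1.0
BENEFICIAL_THRESHOLD = -1.0


def global_align(a: str, b: str, scoring: AlignmentScoring | None = None) -> PairwiseAlignmentResult:
    """Optimal Needleman–Wunsch global alignment with affine gaps."""
    return _align(a, b, "global", scoring)


def read_aligned_fasta(path) -> tuple[str, str]:
    """Accept an externally computed two-sequence alignment verbatim."""
    records = read_fasta_gapped(path)
    if len(records) != 2:
        raise FormatError(f"{path}: aligned FASTA must hold exactly 2 records")
    a, b = records
    if len(a[1]) != len(b[1]):
        raise FormatError(f"{path}: aligned records have different lengths")
    return a[1], b[1]


def read_fasta_gapped(path) -> list[tuple[str, str]]:
    """Minimal gapped-FASTA reader returning (id, aligned sequence) tuples."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq).upper()))
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


@dataclass(frozen=True)
class ProfileColumn:
    col_index: int  # 1-based alignment column
    res_a: str  # residue or '-'
    res_b: str
    agg_a: float | None
    agg_b: float | None
    site_muts_a: tuple = ()
    site_muts_b: tuple = ()


@dataclass(frozen=True)
class AlignedProfile:
    pair_id: str
    columns: tuple

    def ungapped(self, species: str) -> tuple[str, tuple]:
        """Recover (protein, per-residue scores) for one species."""
        res_attr, agg_attr = ("res_a", "agg_a") if species == "a" else ("res_b", "agg_b")
        residues, scores = [], []
        for col in self.columns:
            r = getattr(col, res_attr)
            if r != "-":
                residues.append(r)
                scores.append(getattr(col, agg_attr))
        return "".join(residues), tuple(scores)


def map_profiles(
    gapped_a: str,
    gapped_b: str,
    prof_a: AggregationProfile,
    prof_b: AggregationProfile,
    muts_a: dict | None = None,
    muts_b: dict | None = None,
    pair_id: str = "",
) -> AlignedProfile:
    """Column-wise join of two per-residue profiles through an alignment.

    ``muts_a``/``muts_b`` are per-site landscapes: residue position (1-based)
    -> list of (mutant, mutational Agg_P); only the score values are carried
    onto the columns.
    """
    if len(gapped_a) != len(gapped_b):
        raise ValueError("aligned strings have different lengths")
    for gapped, prof, name in ((gapped_a, prof_a, "A"), (gapped_b, prof_b, "B")):
        n_res = sum(1 for c in gapped if c != "-")
        if n_res != len(prof):
            raise ValueError(
                f"sequence {name}: alignment has {n_res} residues but profile "
                f"has {len(prof)}"
            )
    muts_a = muts_a or {}
    muts_b = muts_b or {}
    columns = []
    ia = ib = 0
    for k, (ca, cb) in enumerate(zip(gapped_a, gapped_b)):
        agg_a = agg_b = None
        site_a: tuple = ()
        site_b: tuple = ()
        if ca != "-":
            ia += 1
            agg_a = float(prof_a.scores[ia - 1])
            site_a = tuple(v for _, v in muts_a.get(ia, ()))
        if cb != "-":
            ib += 1
            agg_b = float(prof_b.scores[ib - 1])
            site_b = tuple(v for _, v in muts_b.get(ib, ()))
        columns.append(
            ProfileColumn(k + 1, ca, cb, agg_a, agg_b, site_a, site_b)
        )
    return AlignedProfile(pair_id=pair_id, columns=tuple(columns))


@dataclass(frozen=True)
class HotspotAnnotation:
    col_index: int
    species: str  # a | b
    kind: str  # beneficial | detrimental
    count: int


def call_hotspots(
    ap: AlignedProfile,
    detrimental_thr: float = DETRIMENTAL_THRESHOLD,
    beneficial_thr: float = BENEFICIAL_THRESHOLD,
) -> list[HotspotAnnotation]:
    """One annotation per (column, species, kind) with the count of site
    mutations strictly beyond the threshold; quiet columns are absent."""
    out = []
    for col in ap.columns:
        for species, muts in (("a", col.site_muts_a), ("b", col.site_muts_b)):
            n_det = sum(1 for v in muts if v > detrimental_thr)
            n_ben = sum(1 for v in muts if v < beneficial_thr)
            if n_ben:
                out.append(HotspotAnnotation(col.col_index, species, "beneficial", n_ben))
            if n_det:
                out.append(HotspotAnnotation(col.col_index, species, "detrimental", n_det))
    return out


def find_indels(gapped_a: str, gapped_b: str) -> list[tuple[str, int, int, int]]:
    """Maximal runs of gap columns per species, in 1-based alignment
    coordinates: (species carrying the gap, start_col, end_col, length)."""
    if len(gapped_a) != len(gapped_b):
        raise ValueError("aligned strings have different lengths")
    out = []
    for species, gapped in (("a", gapped_a), ("b", gapped_b)):
        start = None
        for k, ch in enumerate(gapped):
            if ch == "-" and start is None:
                start = k
            elif ch != "-" and start is not None:
                out.append((species, start + 1, k, k - start))
                start = None
        if start is not None:
            out.append((species, start + 1, len(gapped), len(gapped) - start))
    return sorted(out, key=lambda t: (t[1], t[0]))


def profile_table_rows(ap: AlignedProfile) -> list[dict]:
    """Long-format export rows, one per (column, species); gaps export empty
    aggregation fields plus per-site min/max of the mutational values."""
    rows = []
    for col in ap.columns:
        for species, res, agg, muts in (
            ("a", col.res_a, col.agg_a, col.site_muts_a),
            ("b", col.res_b, col.agg_b, col.site_muts_b),
        ):
            rows.append(
                {
                    "pair_id": ap.pair_id,
                    "col": col.col_index,
                    "species": species,
                    "residue": res,
                    "agg": "" if agg is None else round6(agg),
                    "mut_min": round6(min(muts)) if muts else "",
                    "mut_max": round6(max(muts)) if muts else "",
                    "n_beneficial": sum(1 for v in muts if v < BENEFICIAL_THRESHOLD),
                    "n_detrimental": sum(1 for v in muts if v > DETRIMENTAL_THRESHOLD),
                }
            )
    return rows
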