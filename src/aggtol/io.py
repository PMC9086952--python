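"""Readers and writers for the external formats the pipeline touches.

All on-disk coordinates are 1-based inclusive (Pfam convention); conversion
to Python's 0-based half-open indexing happens exactly here, never further
downstream.  Sequences are uppercased and validated against strict alphabets
on the way in, so the analysis modules can assume clean input.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_LETTERS = frozenset("ACGT")
PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")
STOP_SYMBOL = "*"

_ALPHABETS = {"dna": DNA_LETTERS, "protein": PROTEIN_LETTERS}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# genetic code
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def codon_map(table_id: int = 1) -> dict:
    """Full 64-entry codon -> amino-acid map (stops as '*') for an NCBI table."""
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise FormatError(f"unknown genetic code table id {table_id}") from exc
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP_SYMBOL
    return mapping


@dataclass(frozen=True)
class TranslationResult:
    """Translation of a CDS up to (excluding) its first stop codon.

    ``premature_stop_codon`` is the 1-based codon index of a stop occurring
    before the last codon, or None.  ``terminal_stop`` is True when the final
    codon is a stop and no earlier stop exists.
    """

    protein: str
    premature_stop_codon: int | None
    terminal_stop: bool


def translate(cds: str, table: int = 1) -> TranslationResult:
    """Translate a coding sequence under an NCBI genetic code table.

    The returned protein runs up to but excluding the first stop codon.
    Length must be a multiple of 3; ambiguous bases are rejected.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FormatError(f"CDS length {len(cds)} is not a multiple of 3")
    mapping = codon_map(table)
    n_codons = len(cds) // 3
    residues: list[str] = []
    for c in range(n_codons):
        codon = cds[3 * c : 3 * c + 3]
        aa = mapping.get(codon)
        if aa is None:
            bad = next(i for i, ch in enumerate(codon) if ch not in DNA_LETTERS)
            raise FormatError(
                f"ambiguous or invalid base {codon[bad]!r} at position {3 * c + bad + 1}"
            )
        if aa == STOP_SYMBOL:
            if c == n_codons - 1:
                return TranslationResult("".join(residues), None, True)
            return TranslationResult("".join(residues), c + 1, False)
        residues.append(aa)
    return TranslationResult("".join(residues), None, False)


# ---------------------------------------------------------------------------
# core record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingRecord:
    """A protein-coding nucleotide sequence plus its translation.

    Invariants: len(cds) is a multiple of 3, the protein carries no internal
    stop, and the CDS translates to the protein under ``table``.  A terminal
    stop codon is allowed and recorded; the protein string never contains it.
    """

    id: str
    cds: str
    protein: str
    length_aa: int
    has_terminal_stop: bool = True
    table: int = 1

    @classmethod
    def from_cds(
        cls,
        rec_id: str,
        cds: str,
        table: int = 1,
        expected_protein: str | None = None,
    ) -> "CodingRecord":
        cds = cds.upper()
        tr = translate(cds, table)
        if tr.premature_stop_codon is not None:
            raise FormatError(
                f"{rec_id}: premature stop at codon {tr.premature_stop_codon}; "
                "truncated coding sequences are rejected"
            )
        if expected_protein is not None and tr.protein != expected_protein.upper():
            raise FormatError(
                f"{rec_id}: CDS translation does not match the supplied protein sequence"
            )
        return cls(
            id=rec_id,
            cds=cds,
            protein=tr.protein,
            length_aa=len(tr.protein),
            has_terminal_stop=tr.terminal_stop,
            table=table,
        )


@dataclass(frozen=True)
class DomainAnnotation:
    """A Pfam-style domain interval in 1-based inclusive residue coordinates."""

    protein_id: str
    domain_acc: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"{self.protein_id}/{self.domain_acc}: invalid interval "
                f"{self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def as_slice(self) -> slice:
        """0-based half-open slice over the protein residue array."""
        return slice(self.start - 1, self.end)


@dataclass(frozen=True)
class FastaRecord:
    id: str
    seq: str
    description: str = ""


@dataclass(frozen=True)
class ScoreFile:
    """Per-residue aggregation scores for one protein, as parsed from disk."""

    protein_id: str
    residues: str
    scores: tuple
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.residues):
            raise FormatError(
                f"{self.protein_id}: {len(self.scores)} scores for "
                f"{len(self.residues)} residues"
            )
        for i, s in enumerate(self.scores):
            if not (0.0 <= s <= 100.0) or math.isnan(s):
                raise FormatError(
                    f"{self.protein_id}: score {s} at position {i + 1} outside [0, 100]"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: str) -> list[FastaRecord]:
    """Read a FASTA file with strict alphabet validation.

    Sequences are uppercased; record order is preserved; duplicate ids and
    illegal characters (with their 1-based position) raise FormatError.
    """
    letters = _ALPHABETS.get(alphabet)
    if letters is None:
        raise ValueError(f"alphabet must be one of {sorted(_ALPHABETS)}, got {alphabet!r}")
    path = Path(path)
    records: list[FastaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in letters:
                raise FormatError(
                    f"{path}: record {rec.id!r} has illegal {alphabet} symbol "
                    f"{ch!r} at position {i + 1}"
                )
        records.append(FastaRecord(rec.id, seq, rec.description))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=getattr(r, "description", "") or "")
        for r in records
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in seqs:
            fh.write(f">{rec.id}" + (f" {rec.description}" if rec.description else "") + "\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# per-residue score files
# ---------------------------------------------------------------------------

def read_score_file(
    path,
    dialect: str = "simple",
    protein_id: str | None = None,
    agg_column: str = "Aggregation",
    residue_column: str = "aa",
    position_column: str = "res",
) -> ScoreFile:
    """Read a per-residue aggregation score file.

    ``simple`` is a TSV with header columns position, residue, aggregation.
    ``tango`` is a whitespace-delimited per-residue table as emitted by
    Tango-style predictors; the relevant column names are configurable since
    predictor output headers vary with the run parameters.  Positions must be
    contiguous ascending from 1.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    if dialect == "simple":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        required = {"position", "residue", "aggregation"}
        if not required.issubset(df.columns):
            raise FormatError(f"{path}: simple dialect requires columns {sorted(required)}")
        pos_col, res_col, agg_col = "position", "residue", "aggregation"
        metadata = {}
    elif dialect == "tango":
        df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
        for col in (position_column, residue_column, agg_column):
            if col not in df.columns:
                raise FormatError(f"{path}: tango dialect missing column {col!r}")
        pos_col, res_col, agg_col = position_column, residue_column, agg_column
        metadata = {"columns": list(df.columns)}
    else:
        raise ValueError(f"unknown score-file dialect {dialect!r}")

    positions = df[pos_col].tolist()
    if positions != list(range(1, len(positions) + 1)):
        bad = next(
            (i for i, p in enumerate(positions) if p != i + 1), len(positions) - 1
        )
        raise FormatError(
            f"{path}: position gap or disorder at row {bad + 1} "
            f"(expected {bad + 1}, found {positions[bad]})"
        )
    residues = "".join(str(r) for r in df[res_col])
    scores = tuple(float(s) for s in df[agg_col])
    return ScoreFile(protein_id=protein_id, residues=residues, scores=scores, metadata=metadata)


def write_score_file(score_file: ScoreFile, path) -> None:
    """Write a ScoreFile in the simple dialect; read_score_file inverts it exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("position\tresidue\taggregation\n")
        for i, (res, score) in enumerate(zip(score_file.residues, score_file.scores)):
            fh.write(f"{i + 1}\t{res}\t{score!r}\n")


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTableRow:
    pair_id: str
    protein_id_a: str
    protein_id_b: str
    is_chaperone_client: bool


def read_pair_table(path) -> list[PairTableRow]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pair_id", "protein_id_a", "protein_id_b", "is_chaperone_client"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: pair table requires columns {sorted(required)}")
    if df["pair_id"].duplicated().any():
        dup = df.loc[df["pair_id"].duplicated(), "pair_id"].iloc[0]
        raise FormatError(f"{path}: duplicate pair_id {dup!r}")
    rows = []
    for rec in df.itertuples(index=False):
        flag = str(rec.is_chaperone_client).strip().lower() in {"1", "true", "yes"}
        rows.append(PairTableRow(rec.pair_id, rec.protein_id_a, rec.protein_id_b, flag))
    return rows


def read_domain_table(path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "domain_acc", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: domain table requires columns {sorted(required)}")
    return [
        DomainAnnotation(str(r.protein_id), str(r.domain_acc), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def read_annotation_table(path) -> pd.DataFrame:
    """Protein -> annotation term table with columns protein_id, term_id, aspect."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "term_id", "aspect"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: annotation table requires columns {sorted(required)}")
    bad = set(df["aspect"]) - {"BP", "MF", "CC"}
    if bad:
        raise FormatError(f"{path}: unknown annotation aspects {sorted(bad)}")
    return df[["protein_id", "term_id", "aspect"]]


def read_exclusion_list(path) -> set[str]:
    """Plain-text exclusion list, one protein id per line; '#' starts a comment."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids


def write_results_table(rows, path, columns: list[str] | None = None) -> None:
    """Write result records as a TSV with a deterministic column order.

    Floats are written at fixed 6-decimal precision.  An empty row list
    yields a header-only file (``columns`` must then be given).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dicts = []
    for row in rows:
        if hasattr(row, "__dataclass_fields__"):
            dicts.append({k: getattr(row, k) for k in row.__dataclass_fields__})
        else:
            dicts.append(dict(row))
    if columns is None:
        if not dicts:
            raise ValueError("cannot infer columns from an empty row list")
        columns = list(dicts[0].keys())
    df = pd.DataFrame(dicts, columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def round6(x: float) -> float:
    """Project derived scores onto the 6-decimal grid used for comparisons."""
    return round(float(x), 6)
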