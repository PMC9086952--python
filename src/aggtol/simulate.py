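"""Synthetic ortholog-pair datasets with known ground truth.

The generator emulates the statistical structure the comparative analysis
assumes: pairs of orthologous coding sequences descended from a common
ancestor with controlled nonsynonymous divergence, a subset of pairs
carrying a planted aggregation-prone segment in exactly one species, random
domain intervals, and an annotation table in which one term is enriched
among the planted-differential proteins.  All randomness flows from a
single master seed; each pair draws from its own substream derived by
stable hashing of the pair id, so adding pairs never perturbs existing
ones.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CodingRecord,
    DomainAnnotation,
    FastaRecord,
    PairTableRow,
    codon_map,
    write_fasta,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"

LABEL_UP = "differential_up"
LABEL_DOWN = "differential_down"
LABEL_NULL = "null"


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a scaled-down two-species proteome: 500 ortholog
    pairs of 80–150 residues, 2% nonsynonymous divergence per codon per
    species, 25 pairs carrying a planted 8-residue poly-isoleucine segment
    in exactly one species, and a 20-term annotation vocabulary with one
    term enriched 5-fold among the planted proteins.
    """

    n_pairs: int = 500
    protein_length: tuple = (80, 150)
    background_aa_freqs: dict | None = None  # default: uniform over 20 residues
    nonsyn_rate: float = 0.02
    n_differential: int = 25
    segment_length: int = 8
    segment_residue: str = "I"
    differential_mode: str = "insertion"  # insertion | replacement
    n_client: int = 50
    go_terms: int = 20
    term_rate: float = 0.08
    planted_term_effect: float = 5.0
    seed: int = 0
    table: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.protein_length
        if not (2 <= lo <= hi):
            raise ValueError(f"invalid protein length range {self.protein_length}")
        if self.n_differential > self.n_pairs:
            raise ValueError("n_differential exceeds n_pairs")
        if not (0.0 <= self.nonsyn_rate <= 1.0):
            raise ValueError("nonsyn_rate must be in [0, 1]")
        if self.segment_length >= lo:
            raise ValueError("planted segment longer than the shortest protein")
        if self.segment_residue not in AMINO_ACIDS:
            raise ValueError(f"unknown segment residue {self.segment_residue!r}")
        if self.differential_mode not in {"insertion", "replacement"}:
            raise ValueError(f"unknown differential mode {self.differential_mode!r}")
        if not self.planted_term_effect >= 1.0:
            raise ValueError("planted_term_effect must be >= 1")
        if not (0.0 < min(1.0, self.planted_term_effect * self.term_rate) <= 1.0):
            raise ValueError("term rates out of range")


@dataclass(frozen=True)
class GroundTruth:
    labels: dict  # pair_id -> differential_up | differential_down | null
    planted_term: str
    client_pair_ids: frozenset


@dataclass
class SyntheticDataset:
    config: SimConfig
    records_a: dict  # protein id -> CodingRecord (focal / long-lived species)
    records_b: dict
    pair_rows: list  # PairTableRow
    domains_a: list  # DomainAnnotation on species-A coordinates
    annotations: pd.DataFrame  # protein_id (species A), term_id, aspect
    truth: GroundTruth

    def write(self, out_dir) -> dict:
        """Emit the same plain-text formats the real pipeline consumes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "cds_a": out / "cds_a.fasta",
            "cds_b": out / "cds_b.fasta",
            "pairs": out / "pairs.tsv",
            "domains": out / "domains_a.tsv",
            "annotations": out / "annotations.tsv",
            "exclusions": out / "exclusions.txt",
            "ground_truth": out / "ground_truth.tsv",
        }
        write_fasta(
            [FastaRecord(r.id, r.cds) for r in self.records_a.values()], paths["cds_a"]
        )
        write_fasta(
            [FastaRecord(r.id, r.cds) for r in self.records_b.values()], paths["cds_b"]
        )
        pd.DataFrame(
            [
                {
                    "pair_id": p.pair_id,
                    "protein_id_a": p.protein_id_a,
                    "protein_id_b": p.protein_id_b,
                    "is_chaperone_client": int(p.is_chaperone_client),
                }
                for p in self.pair_rows
            ]
        ).to_csv(paths["pairs"], sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "protein_id": d.protein_id,
                    "domain_acc": d.domain_acc,
                    "start": d.start,
                    "end": d.end,
                }
                for d in self.domains_a
            ]
        ).to_csv(paths["domains"], sep="\t", index=False)
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        paths["exclusions"].write_text("# no excluded proteins\n")
        pd.DataFrame(
            [
                {
                    "pair_id": pid,
                    "label": label,
                    "is_client": int(pid in self.truth.client_pair_ids),
                    "planted_term": self.truth.planted_term,
                }
                for pid, label in self.truth.labels.items()
            ]
        ).to_csv(paths["ground_truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# sequence-level helpers
# ---------------------------------------------------------------------------

def _synonymous_codons(table: int = 1) -> dict:
    by_aa: dict[str, list] = {}
    for codon, aa in sorted(codon_map(table).items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa


def back_translate(protein: str, rng: np.random.Generator, table: int = 1) -> str:
    """Uniform-synonymous-codon back-translation, with one stop codon appended."""
    by_aa = _synonymous_codons(table)
    codons = []
    for i, aa in enumerate(protein):
        options = by_aa.get(aa)
        if options is None or aa == "*":
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
        codons.append(options[rng.integers(len(options))])
    stops = by_aa["*"]
    codons.append(stops[rng.integers(len(stops))])
    return "".join(codons)


def _mutate_codons(cds: str, rng: np.random.Generator, rate: float, table: int) -> str:
    """Independent nonsynonymous substitution per codon at ``rate``; the
    start codon and the stop codon are left untouched and stop-creating or
    synonymous draws are rejected."""
    mapping = codon_map(table)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for c in range(1, len(codons) - 1):
        if rng.random() >= rate:
            continue
        codon = codons[c]
        aa = mapping[codon]
        for _ in range(100):
            j = int(rng.integers(3))
            alt = BASES[int(rng.integers(4))]
            if alt == codon[j]:
                continue
            new_codon = codon[:j] + alt + codon[j + 1 :]
            new_aa = mapping[new_codon]
            if new_aa != "*" and new_aa != aa:
                codons[c] = new_codon
                break
    return "".join(codons)


def _plant_segment(
    cds: str, rng: np.random.Generator, config: SimConfig
) -> str:
    """Insert (or overwrite, in replacement mode) a homopolymer segment of
    the high-scale residue at a random interior codon boundary."""
    by_aa = _synonymous_codons(config.table)
    seg_codons = [
        by_aa[config.segment_residue][rng.integers(len(by_aa[config.segment_residue]))]
        for _ in range(config.segment_length)
    ]
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n_protein = len(codons) - 1  # last codon is the stop
    if config.differential_mode == "insertion":
        at = int(rng.integers(1, n_protein))  # after codon ``at`` (1-based interior)
        codons[at:at] = seg_codons
    else:
        at = int(rng.integers(1, n_protein - config.segment_length))
        codons[at : at + config.segment_length] = seg_codons
    return "".join(codons)


def _pair_rng(seed: int, pair_id: str) -> np.random.Generator:
    sub = zlib.crc32(pair_id.encode("ascii")) & 0x7FFFFFFF
    return np.random.default_rng([seed, sub])


def simulate(config: SimConfig) -> SyntheticDataset:
    """Generate one dataset under ``config`` (deterministic per seed)."""
    master = np.random.default_rng(config.seed)
    aa_list = list(AMINO_ACIDS)
    if config.background_aa_freqs is None:
        freqs = np.full(len(aa_list), 1.0 / len(aa_list))
    else:
        freqs = np.array([config.background_aa_freqs.get(a, 0.0) for a in aa_list])
        if freqs.sum() <= 0:
            raise ValueError("background_aa_freqs has zero total mass")
        freqs = freqs / freqs.sum()

    pair_ids = [f"pair{i:04d}" for i in range(config.n_pairs)]

    # planted labels and client flags come from the master stream
    order = master.permutation(config.n_pairs)
    diff_idx = order[: config.n_differential]
    n_up = (config.n_differential + 1) // 2
    labels = {pid: LABEL_NULL for pid in pair_ids}
    for rank, idx in enumerate(diff_idx):
        labels[pair_ids[idx]] = LABEL_UP if rank < n_up else LABEL_DOWN
    client_idx = master.permutation(config.n_pairs)[: config.n_client]
    client_ids = frozenset(pair_ids[i] for i in client_idx)

    lo, hi = config.protein_length
    records_a: dict[str, CodingRecord] = {}
    records_b: dict[str, CodingRecord] = {}
    pair_rows: list[PairTableRow] = []
    domains: list[DomainAnnotation] = []
    ann_rows: list[dict] = []

    aspects = ["BP", "MF", "CC"]
    term_ids = [f"GO:{i + 1:07d}" for i in range(config.go_terms)]
    term_aspects = {t: aspects[i % 3] for i, t in enumerate(term_ids)}
    planted_term = term_ids[0]  # a BP term, recorded in the ground truth
    planted_rate = min(1.0, config.planted_term_effect * config.term_rate)

    for i, pair_id in enumerate(pair_ids):
        rng = _pair_rng(config.seed, pair_id)
        length = int(rng.integers(lo, hi + 1))
        ancestor = "M" + "".join(
            aa_list[k] for k in rng.choice(len(aa_list), size=length - 1, p=freqs)
        )
        ancestor_cds = back_translate(ancestor, rng, config.table)
        cds_a = _mutate_codons(ancestor_cds, rng, config.nonsyn_rate, config.table)
        cds_b = _mutate_codons(ancestor_cds, rng, config.nonsyn_rate, config.table)
        label = labels[pair_id]
        if label == LABEL_UP:
            cds_a = _plant_segment(cds_a, rng, config)
        elif label == LABEL_DOWN:
            cds_b = _plant_segment(cds_b, rng, config)

        id_a, id_b = f"spA_{i:04d}", f"spB_{i:04d}"
        rec_a = CodingRecord.from_cds(id_a, cds_a, config.table)
        rec_b = CodingRecord.from_cds(id_b, cds_b, config.table)
        records_a[id_a] = rec_a
        records_b[id_b] = rec_b
        pair_rows.append(PairTableRow(pair_id, id_a, id_b, pair_id in client_ids))

        # 1-3 domain intervals on the species-A protein
        for d in range(int(rng.integers(1, 4))):
            dlen = int(rng.integers(10, 31))
            dlen = min(dlen, rec_a.length_aa)
            start = int(rng.integers(1, rec_a.length_aa - dlen + 2))
            domains.append(
                DomainAnnotation(id_a, f"PF{int(rng.integers(1, 100)):05d}", start, start + dlen - 1)
            )

        # annotation terms at background rate; the planted term is enriched
        # among differential proteins
        for term in term_ids:
            rate = (
                planted_rate
                if term == planted_term and label != LABEL_NULL
                else config.term_rate
            )
            if rng.random() < rate:
                ann_rows.append(
                    {"protein_id": id_a, "term_id": term, "aspect": term_aspects[term]}
                )

    annotations = pd.DataFrame(ann_rows, columns=["protein_id", "term_id", "aspect"])
    truth = GroundTruth(
        labels=labels, planted_term=planted_term, client_pair_ids=client_ids
    )
    return SyntheticDataset(
        config=config,
        records_a=records_a,
        records_b=records_b,
        pair_rows=pair_rows,
        domains_a=domains,
        annotations=annotations,
        truth=truth,
    )
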