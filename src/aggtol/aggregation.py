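"""Per-residue aggregation-propensity prediction and score aggregation.

The pipeline is predictor-agnostic: any callable mapping a protein string to
a per-residue score vector in [0, 100] can drive it.  Two providers ship
here — a windowed hydropathy surrogate (fully specified, deterministic, and
cheap enough for saturation mutagenesis) and profiles parsed from external
score files (e.g. Tango output).  Whole-protein and per-domain scores are
length-normalised sums of the per-residue values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .io import DomainAnnotation, ScoreFile, round6


@dataclass(frozen=True)
class AggregationProfile:
    """Per-residue aggregation-propensity scores for one protein."""

    protein_id: str
    scores: tuple
    source: str = "surrogate"  # {surrogate, file}

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.size and (arr.min() < 0.0 or arr.max() > 100.0):
            raise ValueError(f"{self.protein_id}: per-residue scores outside [0, 100]")

    def __len__(self) -> int:
        return len(self.scores)

    @classmethod
    def from_score_file(cls, sf: ScoreFile) -> "AggregationProfile":
        return cls(protein_id=sf.protein_id, scores=tuple(sf.scores), source="file")


@dataclass
class SurrogateParams:
    """Parameters of the windowed-hydropathy surrogate predictor.

    ``scale`` maps each of the 20 standard residues to a real propensity
    weight (default: Kyte–Doolittle hydropathy).  ``window`` is the odd
    averaging window width; ``theta`` the activation threshold on the window
    mean; ``smax`` the scale value mapped to a score of 100.
    """

    scale: dict = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    window: int = 5
    theta: float = 2.0
    smax: float | None = None

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 1, got {self.window}")
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.scale)
        if missing:
            raise ValueError(f"scale missing residues {sorted(missing)}")
        if self.smax is None:
            self.smax = max(self.scale.values())
        if not self.theta < self.smax:
            raise ValueError(f"theta ({self.theta}) must be below smax ({self.smax})")


class SurrogatePredictor:
    """Deterministic per-residue aggregation scorer.

    For residue i the window W_i = [max(1, i-w//2), min(L, i+w//2)] is
    truncated at the termini (no padding), raw_i is the mean scale value over
    W_i, and the score is 0 when raw_i <= theta, else
    100 * min(1, (raw_i - theta) / (smax - theta)).
    """

    def __init__(self, params: SurrogateParams | None = None):
        self.params = params or SurrogateParams()
        self._table = np.full(128, np.nan)
        for aa, value in self.params.scale.items():
            self._table[ord(aa)] = value

    @staticmethod
    @lru_cache(maxsize=256)
    def _window_bounds(length: int, window: int) -> tuple:
        # truncated-window [lo, hi) bounds per residue, shared across calls
        half = window // 2
        idx = np.arange(length)
        lo = np.maximum(0, idx - half)
        hi = np.minimum(length, idx + half + 1)
        return lo, hi, (hi - lo).astype(float)

    def scale_values(self, protein: str) -> np.ndarray:
        """Scale value per residue; raises on any non-standard residue."""
        if not protein:
            raise ValueError("empty protein sequence")
        idx = np.frombuffer(protein.encode("ascii"), dtype=np.uint8)
        values = self._table[idx]
        if np.isnan(values).any():
            pos = int(np.argmax(np.isnan(values)))
            raise ValueError(f"unknown residue {protein[pos]!r} at position {pos + 1}")
        return values

    def scores_from_values(self, values: np.ndarray) -> np.ndarray:
        p = self.params
        lo, hi, counts = self._window_bounds(len(values), p.window)
        cumsum = np.concatenate(([0.0], np.cumsum(values)))
        raw = (cumsum[hi] - cumsum[lo]) / counts
        scaled = 100.0 * np.minimum(1.0, (raw - p.theta) / (p.smax - p.theta))
        return np.where(raw <= p.theta, 0.0, scaled)

    def __call__(self, protein: str) -> np.ndarray:
        return self.scores_from_values(self.scale_values(protein))

    def profile(self, protein_id: str, protein: str) -> AggregationProfile:
        return AggregationProfile(
            protein_id=protein_id, scores=tuple(self(protein)), source="surrogate"
        )


def surrogate_scores(
    protein: str, params: SurrogateParams | None = None, protein_id: str = ""
) -> AggregationProfile:
    """Convenience wrapper building one profile with a fresh predictor."""
    return SurrogatePredictor(params).profile(protein_id, protein)


def agg_p(profile: AggregationProfile) -> float:
    """Whole-protein aggregation score: sum of per-residue scores / length."""
    if len(profile) == 0:
        raise ValueError(f"{profile.protein_id}: empty profile")
    return round6(float(np.mean(profile.scores)))


def agg_d(profile: AggregationProfile, domain: DomainAnnotation) -> float:
    """Per-domain aggregation score: sum over the domain interval / domain length."""
    if domain.end > len(profile):
        raise ValueError(
            f"{profile.protein_id}: domain {domain.domain_acc} "
            f"({domain.start}..{domain.end}) exceeds protein length {len(profile)}"
        )
    segment = np.asarray(profile.scores[domain.as_slice()], dtype=float)
    return round6(float(np.mean(segment)))


# ---------------------------------------------------------------------------
# domain transfer by alignment projection
# ---------------------------------------------------------------------------

def alignment_position_map(gapped_a: str, gapped_b: str) -> list[tuple[int | None, int | None]]:
    """Per-column (a_pos, b_pos) in 1-based residue coordinates, None at gaps."""
    if len(gapped_a) != len(gapped_b):
        raise ValueError("aligned strings have different lengths")
    out = []
    ia = ib = 0
    for ca, cb in zip(gapped_a, gapped_b):
        pa = pb = None
        if ca != "-":
            ia += 1
            pa = ia
        if cb != "-":
            ib += 1
            pb = ib
        out.append((pa, pb))
    return out


def project_domains(
    domains: list[DomainAnnotation],
    gapped_a: str,
    gapped_b: str,
    target_ids: dict | None = None,
) -> tuple[list[DomainAnnotation], list[tuple[DomainAnnotation, str]]]:
    """Project domain intervals from sequence A onto sequence B coordinates.

    The alignment must cover both full sequences (global).  A boundary that
    falls in a gap snaps to the nearest aligned residue inside the domain;
    a domain whose entire interval is deleted in B is dropped and reported.
    ``target_ids`` optionally maps A protein ids to B protein ids for the
    projected annotations.
    """
    colmap = alignment_position_map(gapped_a, gapped_b)
    len_a = sum(1 for c in gapped_a if c != "-")
    a_to_b: dict[int, int | None] = {
        pa: pb for pa, pb in colmap if pa is not None
    }
    projected: list[DomainAnnotation] = []
    dropped: list[tuple[DomainAnnotation, str]] = []
    for dom in domains:
        if dom.end > len_a:
            raise ValueError(
                f"{dom.protein_id}/{dom.domain_acc}: interval exceeds aligned "
                f"sequence length {len_a}"
            )
        b_positions = [
            a_to_b[p] for p in range(dom.start, dom.end + 1) if a_to_b[p] is not None
        ]
        if not b_positions:
            dropped.append((dom, "deleted in target sequence"))
            continue
        new_id = (target_ids or {}).get(dom.protein_id, dom.protein_id)
        projected.append(
            DomainAnnotation(
                protein_id=new_id,
                domain_acc=dom.domain_acc,
                start=min(b_positions),
                end=max(b_positions),
            )
        )
    return projected, dropped
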