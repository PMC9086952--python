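"""Cross-species aggregation deltas, z-score classification, and the
statistical tests used throughout the comparative analysis.

Deltas (species A − species B) are standardized with the sample (n−1)
standard deviation over the full analyzed set at each level; |z| > 2 labels
a unit significantly higher/lower in species A.  Protein-level and
domain-level standardizations are independent, and domain z-scores are
computed over all domains pooled.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import round6

Z_THRESHOLD = 2.0

CLASS_HIGHER = "higher"
CLASS_LOWER = "lower"
CLASS_SIMILAR = "similar"


def zscores(values) -> np.ndarray:
    """Standardize with the sample mean and sample (ddof=1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values to standardize")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero standard deviation; z-scores undefined")
    return (arr - arr.mean()) / sd


def classify_z(z: float, threshold: float = Z_THRESHOLD) -> str:
    if z > threshold:
        return CLASS_HIGHER
    if z < -threshold:
        return CLASS_LOWER
    return CLASS_SIMILAR


@dataclass(frozen=True)
class DeltaRecord:
    """A cross-species score difference with its z-score and class label."""

    unit_id: str | tuple
    level: str  # protein | domain
    value_a: float
    value_b: float
    delta: float
    z: float
    cls: str


def delta_and_classify(
    unit_ids,
    values_a,
    values_b,
    level: str = "protein",
    z_threshold: float = Z_THRESHOLD,
) -> list[DeltaRecord]:
    """Per-unit delta (A − B), standardized over this level's full set."""
    unit_ids = list(unit_ids)
    va = [float(v) for v in values_a]
    vb = [float(v) for v in values_b]
    if not (len(unit_ids) == len(va) == len(vb)):
        raise ValueError("unit ids and value lists must have equal lengths")
    deltas = [round6(a - b) for a, b in zip(va, vb)]
    z = zscores(deltas)
    return [
        DeltaRecord(
            unit_id=uid,
            level=level,
            value_a=a,
            value_b=b,
            delta=d,
            z=round6(zi),
            cls=classify_z(zi, z_threshold),
        )
        for uid, a, b, d, zi in zip(unit_ids, va, vb, deltas, z)
    ]


def summarize_classification(
    protein_records=None,
    domain_records=None,
    domain_owner=None,
) -> dict:
    """Counts of higher/lower units per level plus the union of distinct
    proteins that are significant at either level.

    ``domain_owner`` maps a domain record's unit_id to its owning protein id;
    when a domain unit_id is a (protein, domain) tuple the first element is
    used by default.
    """
    protein_records = protein_records or []
    domain_records = domain_records or []

    def owner(rec):
        if domain_owner is not None:
            return domain_owner[rec.unit_id]
        if isinstance(rec.unit_id, tuple):
            return rec.unit_id[0]
        return rec.unit_id

    sig_proteins = {r.unit_id for r in protein_records if r.cls != CLASS_SIMILAR}
    sig_domains = [r for r in domain_records if r.cls != CLASS_SIMILAR]
    summary = {
        "n_protein_higher": sum(1 for r in protein_records if r.cls == CLASS_HIGHER),
        "n_protein_lower": sum(1 for r in protein_records if r.cls == CLASS_LOWER),
        "n_domain_higher": sum(1 for r in domain_records if r.cls == CLASS_HIGHER),
        "n_domain_lower": sum(1 for r in domain_records if r.cls == CLASS_LOWER),
        "n_domains_significant": len(sig_domains),
        "n_proteins_with_significant_domain": len({owner(r) for r in sig_domains}),
    }
    summary["n_distinct_proteins"] = len(
        sig_proteins | {owner(r) for r in sig_domains}
    )
    return summary


# ---------------------------------------------------------------------------
# classical tests (thin validated wrappers over scipy)
# ---------------------------------------------------------------------------

def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal lengths")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def ks_2samp(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic D and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def t_test(x, y) -> tuple[float, float]:
    """Two-sided two-sample Student's t-test with pooled variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
        x.size + y.size - 2
    )
    if pooled == 0.0:
        raise ValueError("zero pooled variance; t statistic undefined")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)
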