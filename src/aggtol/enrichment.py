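"""Local annotation-term enrichment and the chaperone-subset comparison.

Replaces a web enrichment service with a fully local analysis on a
user-supplied protein -> term table: per-term two-sided Fisher exact tests
on the 2x2 subset/background table, fold enrichment, Benjamini–Hochberg FDR
within each annotation aspect, and a minimum subset-hit filter applied
before testing.  A per-term chi-square compares how two protein groups
(e.g. chaperone clients vs the rest) distribute over terms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import round6

MIN_PROTEINS = 5


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    aspect: str
    k: int  # term hits in the subset
    n: int  # subset size
    K: int  # term hits in the background
    N: int  # background size
    fold_enrichment: float
    log2_fe: float
    p: float
    fdr: float
    direction: str  # enriched | depleted


def bh_fdr(pvalues) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    pvals = [float(p) for p in pvalues]
    for p in pvals:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    if not pvals:
        return []
    return [float(q) for q in multipletests(pvals, method="fdr_bh")[1]]


def fisher_two_sided(k: int, n: int, K: int, N: int) -> float:
    """Two-sided Fisher exact p for the table (k, n-k, K-k, N-n-K+k)."""
    table = [[k, n - k], [K - k, N - n - (K - k)]]
    if min(min(row) for row in table) < 0:
        raise ValueError(f"inconsistent contingency counts k={k} n={n} K={K} N={N}")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def enrich(
    subset,
    background,
    annotations: pd.DataFrame,
    min_proteins: int = MIN_PROTEINS,
    display_only_filter: bool = False,
) -> list[EnrichmentRow]:
    """Term enrichment of ``subset`` against ``background``.

    ``annotations`` has columns protein_id, term_id, aspect.  Terms with
    fewer than ``min_proteins`` subset hits are excluded from the tested
    universe before FDR correction (set ``display_only_filter`` to test and
    correct everything and only then drop small terms).  FDR is computed
    within each aspect separately.  Rows are sorted by (aspect, fdr, p,
    term_id) for deterministic output.
    """
    subset = set(subset)
    background = set(background)
    if not subset <= background:
        extra = sorted(subset - background)[:3]
        raise ValueError(f"subset ids not in background, e.g. {extra}")
    n, N = len(subset), len(background)
    ann = annotations[annotations["protein_id"].isin(background)]

    rows: list[EnrichmentRow] = []
    for aspect, group in ann.groupby("aspect"):
        term_hits = group.groupby("term_id")["protein_id"].agg(set)
        tested = []
        for term_id, proteins in sorted(term_hits.items()):
            K = len(proteins)
            k = len(proteins & subset)
            if not display_only_filter and k < min_proteins:
                continue
            p = fisher_two_sided(k, n, K, N)
            fe = (k / n) / (K / N) if K > 0 and n > 0 else float("nan")
            tested.append((term_id, k, K, p, fe))
        if not tested:
            continue
        fdrs = bh_fdr([max(t[3], 1e-300) for t in tested])
        for (term_id, k, K, p, fe), fdr in zip(tested, fdrs):
            if display_only_filter and k < min_proteins:
                continue
            rows.append(
                EnrichmentRow(
                    term_id=term_id,
                    aspect=aspect,
                    k=k,
                    n=n,
                    K=K,
                    N=N,
                    fold_enrichment=round6(fe),
                    log2_fe=round6(np.log2(fe)) if fe > 0 else float("-inf"),
                    p=p,
                    fdr=fdr,
                    direction="enriched" if fe > 1.0 else "depleted",
                )
            )
    rows.sort(key=lambda r: (r.aspect, r.fdr, r.p, r.term_id))
    return rows


@dataclass(frozen=True)
class SubsetComparisonRow:
    term_id: str
    chi2: float  # nan when the Fisher fallback fired
    p: float
    fdr: float
    used_fisher: bool


def subset_distribution_test(
    counts_client,
    counts_other,
    term_ids=None,
) -> list[SubsetComparisonRow]:
    """Per-term 2x2 chi-square of client vs other proteins, in-term vs
    out-of-term, BH-corrected across terms.

    When any expected cell is zero the chi-square is undefined and the term
    falls back to a Fisher exact test, flagged in the output.
    """
    cc = [int(c) for c in counts_client]
    co = [int(c) for c in counts_other]
    if len(cc) != len(co):
        raise ValueError("count lists must be aligned")
    term_ids = list(term_ids) if term_ids is not None else [f"term{i}" for i in range(len(cc))]
    total_c, total_o = sum(cc), sum(co)
    if total_c <= 0 or total_o <= 0:
        raise ValueError("both groups need positive totals")

    results = []
    for term, c, o in zip(term_ids, cc, co):
        table = np.array([[c, total_c - c], [o, total_o - o]], dtype=float)
        expected = sps.contingency.expected_freq(table)
        if (expected == 0).any():
            p = float(sps.fisher_exact(table.astype(int))[1])
            results.append((term, float("nan"), p, True))
        else:
            chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
            results.append((term, float(chi2), float(p), False))
    fdrs = bh_fdr([max(r[2], 1e-300) for r in results])
    return [
        SubsetComparisonRow(term_id=t, chi2=chi2, p=p, fdr=fdr, used_fisher=fl)
        for (t, chi2, p, fl), fdr in zip(results, fdrs)
    ]
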