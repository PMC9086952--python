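"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive and kept independent of the code
paths it checks: full re-translation for mutagenesis, explicit Gotoh DP for
alignments, textbook formulas for the statistics, and exact integer
combinatorics for the Fisher test.
"""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"


# ---------------------------------------------------------------------------
# naive single-nucleotide mutagenesis
# ---------------------------------------------------------------------------

def naive_translate(cds: str) -> str:
    """Protein up to the first stop, via biopython's translation."""
    full = str(Seq(cds).translate())
    return full.split("*")[0]


def naive_mutant_sets(cds: str):
    """Enumerate all 3L mutants by rebuilding and re-translating each CDS.

    Returns (classification counts, distinct qualifying proteins,
    list of (nt_pos, ref, alt, outcome)).
    """
    wt_protein = naive_translate(cds)
    counts = {"synonymous": 0, "start_loss": 0, "length_change": 0}
    distinct = set()
    events = []
    for i, ref in enumerate(cds):
        for alt in BASES:
            if alt == ref:
                continue
            mutant_cds = cds[:i] + alt + cds[i + 1 :]
            prot = naive_translate(mutant_cds)
            if prot == wt_protein:
                outcome = "synonymous"
            elif not prot or prot[0] != "M":
                outcome = "start_loss"
            elif len(prot) != len(wt_protein):
                outcome = "length_change"
            else:
                outcome = "qualifying"
                distinct.add(prot)
            if outcome != "qualifying":
                counts[outcome] += 1
            events.append((i + 1, ref, alt, outcome))
    return counts, distinct, events


# ---------------------------------------------------------------------------
# affine-gap alignment DP (Gotoh)
# ---------------------------------------------------------------------------

NEG = -1e18


def gotoh_global(a: str, b: str, matrix, open_pen: float, ext_pen: float) -> float:
    """Optimal global alignment score; a gap of length k costs
    open_pen + (k-1) * ext_pen, end gaps included."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(open_pen + (i - 1) * ext_pen)
    for j in range(1, m + 1):
        Y[0][j] = -(open_pen + (j - 1) * ext_pen)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_pen, X[i - 1][j] - ext_pen,
                          Y[i - 1][j] - open_pen)
            Y[i][j] = max(M[i][j - 1] - open_pen, Y[i][j - 1] - ext_pen,
                          X[i][j - 1] - open_pen)
    return max(M[n][m], X[n][m], Y[n][m])


def gotoh_local(a: str, b: str, matrix, open_pen: float, ext_pen: float) -> float:
    """Optimal Smith–Waterman local alignment score under affine gaps."""
    n, m = len(a), len(b)
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i - 1][j - 1] + s,
                          Y[i - 1][j - 1] + s)
            X[i][j] = max(M[i - 1][j] - open_pen, X[i - 1][j] - ext_pen)
            Y[i][j] = max(M[i][j - 1] - open_pen, Y[i][j - 1] - ext_pen)
            best = max(best, M[i][j])
    return best


# ---------------------------------------------------------------------------
# textbook statistics
# ---------------------------------------------------------------------------

def pearson_oracle(x, y):
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x - x.mean(), y - y.mean()
    r = float(np.sum(sx * sy) / math.sqrt(np.sum(sx**2) * np.sum(sy**2)))
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * float(tdist.sf(abs(t), n - 2))
    return r, p


def ks_oracle(x, y) -> float:
    """Two-sample KS D by sweeping both empirical CDFs over all data points."""
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    d = 0.0
    for v in np.concatenate([x, y]):
        fx = np.searchsorted(x, v, side="right") / len(x)
        fy = np.searchsorted(y, v, side="right") / len(y)
        d = max(d, abs(fx - fy))
    return d


def t_oracle(x, y):
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2.0 * float(tdist.sf(abs(t), nx + ny - 2))
    return t, p


def fisher_oracle(k: int, n: int, K: int, N: int) -> float:
    """Two-sided Fisher p as an exact hypergeometric tail sum: the total
    probability of all tables at most as probable as the observed one,
    computed with exact integer combinatorics."""
    def weight(x: int) -> int:
        return math.comb(K, x) * math.comb(N - K, n - x)

    lo, hi = max(0, n - (N - K)), min(n, K)
    w_obs = weight(k)
    total = math.comb(N, n)
    acc = Fraction(0)
    for x in range(lo, hi + 1):
        if weight(x) <= w_obs:
            acc += Fraction(weight(x), total)
    return float(acc)


def chi2_oracle(table):
    """Pearson chi-square Sigma (O-E)^2 / E on a 2x2 table, no correction."""
    from scipy.stats import chi2 as chi2dist

    obs = np.asarray(table, float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    stat = float(np.sum((obs - expected) ** 2 / expected))
    return stat, float(chi2dist.sf(stat, 1))


def bh_oracle(pvals):
    """BH step-up: sort, scale by m/rank, take running min from the largest."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted
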