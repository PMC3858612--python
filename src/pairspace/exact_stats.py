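"""Exact small-sample nonparametric tests.

With seven dyads, asymptotic rank-test p-values are unreliable, so the
signed-rank and rank-sum nulls are evaluated exactly: the full reference
distribution over all 2^n sign assignments (signed-rank) or all C(n1+n2, n1)
group labelings (rank-sum) is computed by subset-sum dynamic programming,
which enumerates the same distribution without materializing every
assignment. Two-sided p-values are twice the smaller tail, capped at 1 —
for seven all-positive differences (V at its maximum of 28) this gives
p = 2/2^7 = 0.015625, i.e. 0.02 at two decimals.

Mid-ranks are used for tied absolute values; zeros are dropped before
ranking (signed-rank). Beyond the exact-enumeration caps the tests fall
back to the tie-corrected normal approximation with a logged notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

__all__ = [
    "TestResult",
    "signed_rank_exact",
    "rank_sum_exact",
    "chi2_independence_2x2",
]

log = logging.getLogger(__name__)

MAX_EXACT_SIGNED_RANK = 25
MAX_EXACT_RANK_SUM = 20


@dataclass
class TestResult:
    statistic: float
    n: int
    p_two_sided: float
    method: str

    def __post_init__(self) -> None:
        if not 0 < self.p_two_sided <= 1:
            raise ValueError(f"p out of (0, 1]: {self.p_two_sided}")


def _subset_sum_counts(weights: np.ndarray) -> np.ndarray:
    """counts[s] = number of subsets of ``weights`` (nonneg ints) summing to s."""
    total = int(weights.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for w in weights:
        w = int(w)
        if w == 0:
            counts *= 2
        else:
            counts[w:] = counts[w:] + counts[:-w]
    return counts


def signed_rank_exact(differences) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test.

    The statistic V is the sum of ranks of positive differences (zeros
    dropped, mid-ranks for ties). For n <= 25 the p-value is exact over all
    2^n equally likely sign assignments.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("test undefined: all differences are zero")
    ranks = rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    if n <= MAX_EXACT_SIGNED_RANK:
        r2 = np.rint(2 * ranks).astype(int)  # doubled ranks are integers even with mid-ranks
        counts = _subset_sum_counts(r2)
        v2 = int(round(2 * v))
        denom = 2.0**n
        p_le = counts[: v2 + 1].sum() / denom
        p_ge = counts[v2:].sum() / denom
        p = min(1.0, 2 * min(p_le, p_ge))
        method = "wilcoxon-signed-rank exact"
    else:
        log.info("signed-rank n=%d > %d: normal approximation", n, MAX_EXACT_SIGNED_RANK)
        mu = n * (n + 1) / 4
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
        z = (v - mu) / np.sqrt(var)
        p = min(1.0, 2 * norm.sf(abs(z)))
        method = "wilcoxon-signed-rank normal-approx"
    return TestResult(v, n, max(p, np.finfo(float).tiny), method)


def rank_sum_exact(a, b) -> TestResult:
    """Exact two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic W is the Mann-Whitney count for sample ``a``. Without ties
    and with n1+n2 <= 20 the p-value is exact over all C(n1+n2, n1) equally
    likely labelings; ties (or larger samples) force the tie-corrected
    normal approximation with a logged notice.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    w = r1 - n1 * (n1 + 1) / 2  # Mann-Whitney U for sample a
    n = n1 + n2
    has_ties = np.unique(pooled).size < n
    if not has_ties and n <= MAX_EXACT_RANK_SUM:
        # ways[k, s] = number of k-subsets of ranks {1..n} with rank-sum s
        maxsum = n * (n + 1) // 2
        ways = np.zeros((n1 + 1, maxsum + 1))
        ways[0, 0] = 1.0
        for r in range(1, n + 1):
            for k in range(min(n1, r), 0, -1):
                ways[k, r:] = ways[k, r:] + ways[k - 1, :-r]
        dist = ways[n1]
        total = dist.sum()
        r1_int = int(round(r1))
        p_le = dist[: r1_int + 1].sum() / total
        p_ge = dist[r1_int:].sum() / total
        p = min(1.0, 2 * min(p_le, p_ge))
        method = "wilcoxon-rank-sum exact"
    else:
        reason = "ties" if has_ties else f"n={n} > {MAX_EXACT_RANK_SUM}"
        log.info("rank-sum %s: normal approximation", reason)
        mu = n1 * n2 / 2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12 * (n + 1 - tie_term)
        if var == 0:
            p, z = 1.0, 0.0
        else:
            z = (w - mu) / np.sqrt(var)
            p = min(1.0, 2 * norm.sf(abs(z)))
        method = "wilcoxon-rank-sum normal-approx"
    return TestResult(w, n, max(p, np.finfo(float).tiny), method)


def chi2_independence_2x2(table, correction: bool = False) -> TestResult:
    """Chi-squared test of independence for a 2x2 count table (df = 1).

    Yates continuity correction is off by default and available as a flag.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("need a nonnegative 2x2 table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("test undefined: zero row or column margin")
    total = obs.sum()
    expected = np.outer(rows, cols) / total
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / expected).sum())
    p = float(chi2_dist.sf(stat, df=1))
    return TestResult(stat, int(total), max(p, np.finfo(float).tiny),
                      "chi2 independence df=1" + (" (Yates)" if correction else ""))
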