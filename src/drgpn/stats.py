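"""Self-contained nonparametric statistics: Wilcoxon rank-sum, Kruskal-Wallis,
Benjamini-Hochberg.

The rank-sum test enumerates the exact permutation distribution of the
rank-sum when both groups are small and tie-free, and otherwise uses the
normal approximation with tie-corrected variance and a continuity correction.
Mid-ranks are used for ties throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm, rankdata


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _ranksum_null_counts(n: int, total: int) -> np.ndarray:
    """Number of n-subsets of ranks 1..total with each possible rank-sum.

    Dynamic program over (elements chosen, sum); index s of the returned
    vector is the count of subsets summing to s.
    """
    max_sum = total * (total + 1) // 2
    # dp[k][s]: subsets of size k with sum s using ranks seen so far
    dp = np.zeros((n + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in range(1, total + 1):
        # iterate k downward so each rank is used at most once
        for k in range(min(n, r), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum - r + 1]
    return dp[n]


def wilcoxon_rank_sum(x, y, exact_max_n: int = 10) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of the permutation distribution of the rank-sum of
    ``x`` when both group sizes are <= ``exact_max_n`` and there are no ties;
    otherwise a normal approximation with tie-corrected variance and a 0.5
    continuity correction toward the null mean.  If every value is identical
    across both groups the test is degenerate: p = 1, statistic at its null
    mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = x.size, y.size
    total = n + m
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # mid-ranks
    w = float(ranks[:n].sum())
    mean_w = n * (total + 1) / 2.0
    has_ties = np.unique(pooled).size < total

    if not has_ties and n <= exact_max_n and m <= exact_max_n:
        counts = _ranksum_null_counts(n, total)
        sums = np.arange(counts.size, dtype=float)
        dev = np.abs(sums - mean_w)
        obs_dev = abs(w - mean_w)
        # tiny epsilon guards float comparison of half-integer deviations
        p = float(counts[dev >= obs_dev - 1e-9].sum() / counts.sum())
        return TestResult(w, min(p, 1.0), "wilcoxon-rank-sum-exact", True)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var_w = n * m / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    if var_w <= 0:
        return TestResult(mean_w, 1.0, "wilcoxon-rank-sum-normal", False)
    z = (abs(w - mean_w) - 0.5) / np.sqrt(var_w)
    z = max(z, 0.0)
    p = float(2.0 * norm.sf(z))
    return TestResult(w, min(p, 1.0), "wilcoxon-rank-sum-normal", False)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test with tie correction; p from chi-squared (k-1 df).

    Degenerate inputs (all pooled values identical) give H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(groups)
    total = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (total * (total + 1)) * h - 3 * (total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (
        total**3 - total
    )
    if correction <= 0:  # every value identical
        return TestResult(0.0, 1.0, "kruskal-wallis", False)
    h /= correction
    h = max(h, 0.0)
    p = float(chi2.sf(h, df=len(groups) - 1))
    return TestResult(h, min(p, 1.0), "kruskal-wallis", False)


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries are propagated and excluded from the number of tests m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    adj = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[valid] = res
    return out
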