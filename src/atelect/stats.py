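"""Cohort statistics: rank-sum and variance-ratio tests, group summaries.

Group differences in mass/density changes between healthy and atelectatic
lobes are tested with a two-sided, unpaired Wilcoxon rank-sum test; the
difference in variance of dose changes between resolving and non-resolving
patients is tested with a two-sided F-test.  Both use alpha = 0.05.  No
multiple-testing correction is applied.

The rank-sum test switches between an exact permutation distribution
(min(n) <= 10 and no ties in the pooled sample — small cohort groups of
4/5/9 demand exact handling) and the normal approximation with tie and
continuity correction otherwise.  The exact null distribution of the
Mann-Whitney U statistic is computed once per group-size pair with the
classic counting recurrence and cached, which keeps large null
calibrations (10^4 replicates) cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
EXACT_MAX_N = 10


@dataclass(frozen=True)
class GroupComparison:
    test: str                 # "wilcoxon_rank_sum" | "variance_F"
    groups: tuple[str, str]
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str = ""          # "exact" | "normal_approx" | "f_distribution"
    two_sided: bool = True
    alpha: float = ALPHA
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@lru_cache(maxsize=64)
def _exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic for group sizes (n1, n2).

    Counting recurrence: c(m, u) arrangements of m group-1 ranks among the
    first items yielding U = u; built by convolution over group-1 sample
    size, normalized by C(n1 + n2, n1).
    """
    # counts[u] for samples of size m from {adds 0..n2 each step}, classic DP:
    # f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u) implemented iteratively.
    max_u = n1 * n2
    counts = np.zeros((n1 + 1, max_u + 1), dtype=float)
    counts[:, 0] = 1.0  # f(m, 0, u) = [u == 0]
    for n in range(1, n2 + 1):
        new = counts.copy()  # carries f(m, n-1, u)
        for m in range(1, n1 + 1):
            new[m, n:] += new[m - 1, :-n]  # f(m-1, n, u-n)
        counts = new
    pmf = counts[n1]
    return pmf / pmf.sum()


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, bool, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = x.size
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    return u1, has_ties, tie_counts.astype(float)


def wilcoxon_rank_sum(x, y, groups: tuple[str, str] = ("x", "y")) -> GroupComparison:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney) test."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    u1, has_ties, tie_counts = _u_statistic(x, y)
    n1, n2 = x.size, y.size

    if np.all(np.concatenate([x, y]) == x[0]):
        return GroupComparison("wilcoxon_rank_sum", groups, u1, 1.0, n1, n2,
                               method="degenerate", degenerate=True)

    if min(n1, n2) <= EXACT_MAX_N and not has_ties:
        pmf = _exact_u_pmf(n1, n2)
        cdf = np.cumsum(pmf)
        u = int(round(u1))
        lower = cdf[u]
        upper = pmf[u:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        method = "exact"
    else:
        n = n1 + n2
        mean = n1 * n2 / 2.0
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return GroupComparison("wilcoxon_rank_sum", groups, u1, 1.0, n1, n2,
                                   method="degenerate", degenerate=True)
        # continuity correction toward the mean
        diff = u1 - mean
        diff -= 0.5 * np.sign(diff)
        z = diff / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return GroupComparison("wilcoxon_rank_sum", groups, float(u1), float(min(p, 1.0)),
                           n1, n2, method=method)


def variance_f_test(x, y, groups: tuple[str, str] = ("x", "y")) -> GroupComparison:
    """Two-sided F-test for equality of variances (normal theory)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vy == 0:
        raise ValueError("zero variance in denominator group")
    F = vx / vy
    dfx, dfy = x.size - 1, y.size - 1
    cdf = sps.f.cdf(F, dfx, dfy)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return GroupComparison("variance_F", groups, float(F), p, x.size, y.size,
                           method="f_distribution")


def summarize(df: pd.DataFrame, value_col: str, group_col: str) -> pd.DataFrame:
    """Mean / sample stdev (n-1) / n per group for one quantity."""
    rows = []
    for group, grp in df.groupby(group_col, sort=False):
        v = grp[value_col].to_numpy(dtype=float)
        rows.append({
            group_col: group,
            "n": v.size,
            "mean": v.mean(),
            "stdev": v.std(ddof=1) if v.size > 1 else 0.0,
        })
    return pd.DataFrame(rows)


def intra_patient_sd(df: pd.DataFrame, value_col: str, patient_col: str = "patient") -> float:
    """Mean over patients of the stdev across their repeat-scan pairings."""
    sds = []
    for _, grp in df.groupby(patient_col, sort=False):
        v = grp[value_col].to_numpy(dtype=float)
        if v.size > 1:
            sds.append(v.std(ddof=1))
    if not sds:
        return 0.0
    return float(np.mean(sds))
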