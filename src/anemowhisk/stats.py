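"""Small-sample nonparametric tests used across the pipeline.

The group sizes in this kind of study (5-8 animals, 26 whiskers) sit
exactly where the normal approximations of rank tests are poorest, so the
signed-rank and rank-sum tests here compute exact null distributions
(handling midranks from ties) whenever the sample is small enough, and
fall back to the tie-corrected asymptotic test otherwise.  Two-sided
p-values use the doubled-smaller-tail convention, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: Largest n for which the exact signed-rank distribution is enumerated.
EXACT_SIGNED_RANK_N = 25
#: Largest combined n+m for which the exact rank-sum distribution is enumerated.
EXACT_RANK_SUM_N = 25


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p: float
    n: int
    exact: bool


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _two_sided_from_dist(support: np.ndarray, probs: np.ndarray, observed: float) -> float:
    lo = probs[support <= observed + 1e-12].sum()
    hi = probs[support >= observed - 1e-12].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def signed_rank_test(diffs: np.ndarray) -> RankTestResult:
    """Wilcoxon signed-rank test of paired differences against zero.

    Zero differences are dropped (Wilcoxon convention).  If every
    difference is zero the test is vacuous and p = 1 by convention.
    Exact for n <= 25 via dynamic programming over doubled midranks
    (valid with ties); asymptotic normal with tie correction otherwise.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1:
        raise ValueError("diffs must be 1-D")
    if np.isnan(d).any():
        raise ValueError("diffs contain NaN")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return RankTestResult(statistic=0.0, p=1.0, n=0, exact=True)
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_N:
        # doubled ranks are integers even with .5 midranks
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        # dp[s] = #{sign patterns with doubled W+ = s}
        dp = np.zeros(total + 1)
        dp[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dp)
            shifted[r:] = dp[: dp.size - r]
            dp = dp + shifted
        probs = dp / 2.0**n
        support = np.arange(total + 1) / 2.0
        p = _two_sided_from_dist(support, probs, w_plus)
        return RankTestResult(statistic=w_plus, p=p, n=n, exact=True)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_plus - mu) / sigma
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return RankTestResult(statistic=w_plus, p=p, n=n, exact=False)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> RankTestResult:
    """Mann-Whitney/Wilcoxon rank-sum test, two-sided.

    Exact (tie-aware, via DP over doubled midranks) when n+m <= 25,
    else tie-corrected normal approximation without continuity
    correction.  The reported statistic is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    ranks = _midranks(np.concatenate([x, y]))
    rx = float(ranks[:n].sum())
    u = rx - n * (n + 1) / 2.0
    if n + m <= EXACT_RANK_SUM_N:
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        # dp[k][s] = #{subsets of size k with doubled rank-sum s}
        dp = np.zeros((n + 1, total + 1))
        dp[0, 0] = 1.0
        for r in r2:
            for k in range(n, 0, -1):
                dp[k, r:] += dp[k - 1, : total + 1 - r]
        counts = dp[n]
        probs = counts / counts.sum()
        support = np.arange(total + 1) / 2.0
        p = _two_sided_from_dist(support, probs, rx)
        return RankTestResult(statistic=u, p=p, n=n + m, exact=True)
    mu = n * m / 2.0
    big_n = n + m
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (big_n * (big_n - 1))
    sigma = np.sqrt(n * m / 12.0 * (big_n + 1 - tie_term))
    z = (u - mu) / sigma
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return RankTestResult(statistic=u, p=p, n=n + m, exact=False)


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "bonferroni"):
    """Dunn's rank-based post hoc test for all pairwise group contrasts.

    Returns a dict mapping (label_a, label_b) -> two-sided p.  Uses the
    tie-corrected pooled-rank variance; ``adjust`` is "bonferroni" or
    "none".
    """
    labels = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(values)
    big_n = pooled.size
    ranks = _midranks(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for lab, v in zip(labels, values):
        mean_ranks[lab] = ranks[start : start + v.size].mean()
        sizes[lab] = v.size
        start += v.size
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_corr = (tie_counts**3 - tie_counts).sum() / (12.0 * (big_n - 1))
    base_var = big_n * (big_n + 1) / 12.0 - tie_corr
    n_pairs = len(labels) * (len(labels) - 1) // 2
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(1.0, p * n_pairs)
            elif adjust != "none":
                raise ValueError(f"unknown adjustment {adjust!r}")
            out[(a, b)] = float(p)
    return out
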