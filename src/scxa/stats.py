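"""Shared statistical primitives.

Small wrappers that pin down the exact conventions used throughout the
package (two-sidedness, tie handling, zero handling) so that every module
tests the same way.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_signed_rank",
    "mann_whitney",
    "bh_adjust",
    "contingency_chi2",
    "spearman_association",
]

#: sample size up to which the signed-rank test uses the exact permutation
#: distribution; beyond it the normal approximation with tie correction.
EXACT_WILCOXON_MAX_N = 25


def _signed_rank_exact_p(d: np.ndarray) -> float:
    """Tie-aware exact two-sided signed-rank p by dynamic programming.

    The null distribution of W+ = sum of (average) ranks with positive sign
    is built by convolution over doubled ranks (integers even with .5 ties),
    and the two-sided p counts outcomes at least as far from the symmetric
    mean as observed.
    """
    ranks2 = np.round(2 * stats.rankdata(np.abs(d))).astype(int)
    w_obs = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:-r] if r > 0 else dist
        dist = (dist + shifted) / 2.0
    dev = np.abs(np.arange(total + 1) - total / 2.0)
    return float(dist[dev >= np.abs(w_obs - total / 2.0) - 1e-9].sum())


def wilcoxon_signed_rank(values, mu: float = 0.0, zero_method: str = "wilcox") -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value for H0: median = mu.

    Zeros are dropped by default (``zero_method='wilcox'``); ``'pratt'`` keeps
    them in the ranking. Exact (tie-aware) distribution for n <= 25 after
    zero removal, normal approximation with tie correction otherwise. All
    values equal to ``mu`` gives p = 1.
    """
    d = np.asarray(values, dtype=float) - mu
    if d.size == 0:
        raise ValueError("empty sample")
    nonzero = np.count_nonzero(d)
    if nonzero == 0:
        return 1.0
    if zero_method == "wilcox":
        d = d[d != 0]
    if d.size <= EXACT_WILCOXON_MAX_N and zero_method == "wilcox":
        return _signed_rank_exact_p(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            d, zero_method=zero_method, alternative="two-sided", method="approx"
        )
    return float(res.pvalue)


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney rank-sum p-value; p = 1 for identical constants."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contingency_chi2(table):
    """Pearson chi-square (no continuity correction) on a contingency table.

    Returns ``(chi2, df, p)``. A zero row/column margin is degenerate: the
    statistic is 0 with p = 1 and a warning, matching the convention that an
    empty category carries no evidence of association.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin in contingency table; returning chi2=0, p=1")
        return 0.0, df, 1.0
    chi2, p, df, expected = stats.chi2_contingency(t, correction=False)
    if np.any(expected < 5):
        warnings.warn("expected counts < 5; chi-square approximation is poor")
    return float(chi2), int(df), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (small expected counts)."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def _spearman_exact_p(x, y, rho_obs: float) -> float:
    from itertools import permutations

    y = np.asarray(y, dtype=float)
    count = 0
    total = 0
    for perm in permutations(range(len(y))):
        r = stats.spearmanr(x, y[list(perm)]).statistic
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_association(x, y, exact_max_n: int = 8):
    """Spearman rank correlation with average-rank ties.

    Returns ``(rho, p)``; p is by full permutation enumeration for
    n <= ``exact_max_n`` and the t-approximation otherwise. Requires n >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must be aligned")
    if x.size < 3:
        raise ValueError("association undefined for n < 3")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if np.isnan(rho):  # constant input
        return 0.0, 1.0
    if x.size <= exact_max_n:
        p = _spearman_exact_p(x, y, rho)
    return rho, float(p)
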