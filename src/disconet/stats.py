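"""Shared statistical kernels: upper-tail tests, BH adjustment, Mann-Whitney U.

These are thin, explicitly-conventioned wrappers over scipy/statsmodels so
that every module in the pipeline uses identical tail and correction
semantics.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "binom_tail",
    "hypergeom_tail",
    "bh_adjust",
    "mann_whitney",
]


def binom_tail(x: int, n: int, q: float) -> float:
    """Upper-tail binomial probability P(X >= x) for X ~ Binomial(n, q)."""
    if x <= 0:
        return 1.0
    return float(sps.binom.sf(x - 1, n, q))


def hypergeom_tail(x: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    X counts successes in a draw of ``n`` from a population of ``N`` with
    ``K`` successes.
    """
    if x <= 0:
        return 1.0
    return float(sps.hypergeom.sf(x - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# Exact enumeration is used whenever the smaller group is at most this size;
# beyond it the normal approximation with tie correction takes over.
_EXACT_MAX = 10


def mann_whitney(a, b) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by full enumeration of the C(n_a+n_b, n_a) group assignments when
    both groups have <= 10 values (ties handled through midranks), otherwise
    the normal approximation with tie correction.  Two identical multisets
    give p = 1.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if max(a.size, b.size) <= _EXACT_MAX:
        return _exact_mw(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _exact_mw(a: np.ndarray, b: np.ndarray) -> float:
    """Exact permutation distribution of the rank sum via 0/1-knapsack
    counting over doubled midranks (exact with ties, no enumeration)."""
    na = a.size
    ranks2 = np.rint(2.0 * sps.rankdata(np.concatenate([a, b]))).astype(np.int64)
    mu2 = na * ranks2.sum() / (na + b.size)  # doubled mean rank sum of group a
    obs2 = ranks2[:na].sum()
    d_obs = abs(obs2 - mu2)

    maxs = int(ranks2.sum())
    dp = np.zeros((na + 1, maxs + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for j in range(na, 0, -1):
            dp[j, r:] += dp[j - 1, : maxs + 1 - r]
    counts = dp[na]
    sums = np.arange(maxs + 1)
    extreme = np.abs(sums - mu2) >= d_obs - 1e-9
    return float(counts[extreme].sum() / counts.sum())
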