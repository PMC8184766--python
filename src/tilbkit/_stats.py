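"""Rank-sum machinery shared by the per-cell scorer and the marker tests.

The exact mode computes the null distribution of a subset rank-sum over all
C(N, m) placements by a dynamic program on doubled midranks (ties make
midranks half-integral; doubling restores integrality).  It is numerically
identical to exhaustive enumeration but polynomial in N.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata


def midranks(values):
    return rankdata(np.asarray(values, dtype=float))


def tie_term(values):
    """Sum over tie groups of t^3 - t for the tie-corrected variance."""
    _, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t ** 3 - t))


def ranksum_normal_p(rank_sum, m, n_total, ties=0.0, alternative="greater",
                     continuity=True):
    """Normal-approximation p for the sum of m of N midranks.

    Tie-corrected variance; continuity correction of 0.5 on the rank-sum
    scale.  Degenerate (zero-variance) instances return p = 1.
    """
    n = n_total - m
    mu = m * (n_total + 1) / 2.0
    var = m * n / 12.0 * ((n_total + 1) - ties / (n_total * (n_total - 1)))
    if var <= 0:
        return 1.0
    cc = 0.5 if continuity else 0.0
    if alternative == "greater":
        z = (rank_sum - mu - cc) / np.sqrt(var)
        p = norm.sf(z)
    elif alternative == "two-sided":
        z = max(abs(rank_sum - mu) - cc, 0.0) / np.sqrt(var)
        p = 2.0 * norm.sf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def _subset_sum_counts(ranks2, m):
    """counts[s] = number of m-subsets of ranks2 with sum s (ranks2 integral)."""
    n_total = len(ranks2)
    max_sum = int(np.sum(np.sort(ranks2)[-m:]))
    # dp[j, s]: subsets of size j summing to s
    dp = np.zeros((m + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        upper = min(m, n_total)
        for j in range(upper - 1, -1, -1):
            row = dp[j]
            if not row.any():
                continue
            dp[j + 1, r:] += row[: max_sum + 1 - r]
    return dp[m]


def ranksum_exact_p(values_ranks, m, rank_sum, alternative="greater"):
    """Exact p over all C(N, m) rank placements, tie-aware.

    ``values_ranks`` are the midranks of all N observations; ``rank_sum`` is
    the observed sum of the m in-set midranks.
    """
    ranks2 = np.round(2.0 * np.asarray(values_ranks, dtype=float)).astype(int)
    obs2 = int(round(2.0 * rank_sum))
    counts = _subset_sum_counts(ranks2, m)
    total = counts.sum()
    sums = np.arange(len(counts))
    if alternative == "greater":
        tail = counts[sums >= obs2].sum()
    elif alternative == "two-sided":
        n_total = len(ranks2)
        mu2 = m * (n_total + 1)  # doubled mean
        dev = abs(obs2 - mu2)
        tail = counts[np.abs(sums - mu2) >= dev].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(tail / total)


def bh_adjust(pvals):
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out
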