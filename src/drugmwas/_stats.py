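"""Shared statistical primitives.

Thin, well-specified wrappers around scipy/statsmodels routines that several
pipeline stages share: the two-sample rank test used for all user/non-user
contrasts, Benjamini-Hochberg adjustment, and Spearman correlation with an
exact small-sample p-value.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_test", "bh_adjust", "spearman"]

# above this group size the normal approximation (with tie correction) is used
_EXACT_RANKSUM_MAX_N = 50
_EXACT_SPEARMAN_MAX_N = 10


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided two-sample rank-sum (Mann-Whitney U) test.

    Returns ``(statistic, p)``.  Exact enumeration of the rank-sum null is
    used when both groups have at most 50 observations and there are no ties;
    otherwise the normal approximation with tie correction is applied.
    Degenerate inputs (either group empty) raise ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires at least one observation per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = max(x.size, y.size) <= _EXACT_RANKSUM_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    Order-preserving with the input vector.  Values outside [0, 1] raise.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _exact_spearman_p(rho_obs: float, ranks_x: np.ndarray, ranks_y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman's rho at n <= 10."""
    n = ranks_x.size
    rx = (ranks_x - ranks_x.mean()) / ranks_x.std()
    ry = (ranks_y - ranks_y.mean()) / ranks_y.std()
    count = 0
    total = 0
    chunk = []
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 40320:  # flush in blocks to keep memory bounded
            idx = np.array(chunk)
            rhos = (rx[idx] * ry).mean(axis=1)
            count += int(np.sum(np.abs(rhos) >= target))
            total += len(chunk)
            chunk = []
    if chunk:
        idx = np.array(chunk)
        rhos = (rx[idx] * ry).mean(axis=1)
        count += int(np.sum(np.abs(rhos) >= target))
        total += len(chunk)
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie-corrected ranks.

    Two-sided p-value: exact permutation enumeration for n <= 10, the t
    approximation otherwise.  Constant input vectors raise ``ValueError``
    (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p_t = stats.spearmanr(x, y)
    if x.size <= _EXACT_SPEARMAN_MAX_N:
        ranks_x = stats.rankdata(x)
        ranks_y = stats.rankdata(y)
        return float(rho), float(_exact_spearman_p(rho, ranks_x, ranks_y))
    return float(rho), float(p_t)


def round_half_away(x) -> np.ndarray:
    """Round half away from zero (3.5 -> 4, -3.5 -> -4), unlike banker's rounding."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)
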