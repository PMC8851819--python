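"""Statistical kernels: Wilcoxon rank-sum / Mann-Whitney U and
Fisher-transform averaging of correlation coefficients.

The rank-sum test is implemented here (rather than delegated) because the
small-sample path must enumerate the exact permutation distribution with
the U = #(x > y) + 1/2 #(x = y) tie convention; the normal-approximation
path applies the standard tie correction and a 0.5 continuity correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["RankSumResult", "rank_sum_test", "mann_whitney_u", "fisher_average"]

EXACT_MAX_N = 8  # exact enumeration when both samples are this size or less


@dataclass(frozen=True)
class RankSumResult:
    u: float  # U statistic of the first sample
    p_value: float
    method: str  # "exact" or "normal"


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """U statistic of x over y: #(x_i > y_j) pairs plus half the ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    # rank-based computation, equivalent to pair counting
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    # average ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = (i + j + 2) / 2.0
        i = j + 1
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _u_from_ranksum(ranks_sum: float, n1: int) -> float:
    return ranks_sum - n1 * (n1 + 1) / 2.0


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation enumeration when both samples have at most
    ``EXACT_MAX_N`` observations (ties handled by the 1/2 convention,
    two-sided p = min(1, 2 * min(P(U <= u), P(U >= u)))); otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u = mann_whitney_u(x, y)

    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        # U of a relabeling depends only on the rank sum of the genes chosen
        # as "sample 1", so enumerate rank-sum combinations directly.
        pooled = np.concatenate([x, y])
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        le = ge = total = 0
        for comb in itertools.combinations(ranks.tolist(), n1):
            u_perm = sum(comb) - offset
            total += 1
            if u_perm <= u + 1e-12:
                le += 1
            if u_perm >= u - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le / total, ge / total))
        return RankSumResult(u=u, p_value=p, method="exact")

    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return RankSumResult(u=u, p_value=1.0, method="normal")
    z = (u - mu - math.copysign(0.5, u - mu)) / math.sqrt(sigma2) if u != mu else 0.0
    p = min(1.0, 2.0 * _norm_sf(abs(z)))
    return RankSumResult(u=u, p_value=p, method="normal")


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def fisher_average(rhos: Sequence[float]) -> float:
    """Average correlations through the Fisher z transform.

    Each rho of exactly +/-1 is first nudged to the next representable
    float toward zero (atanh(+/-1) is infinite); the result is
    tanh(mean(atanh(rho))), strictly inside (-1, 1).
    """
    r = np.asarray(rhos, dtype=float)
    if r.size == 0:
        raise ValueError("no correlations to average")
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must be in [-1, 1]")
    r = np.where(r == 1.0, np.nextafter(1.0, 0.0), r)
    r = np.where(r == -1.0, np.nextafter(-1.0, 0.0), r)
    return float(np.tanh(np.mean(np.arctanh(r))))
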