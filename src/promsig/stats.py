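"""Shared statistical primitives (rank-sum engine, AUC)."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["rank_sum_test", "auc"]

#: combined sample size at or below which the exact permutation null is used
EXACT_RANKSUM_MAX_N = 20


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Returns ``(z, p)`` where ``z`` is the tie-corrected standardized rank sum
    of ``a`` (sign flips when the samples are swapped). For combined sample
    sizes up to 20 the p-value comes from exhaustive enumeration of all rank
    splits (valid under ties); larger samples use the normal approximation
    with continuity and tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0

    # tie-corrected variance of the rank sum
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0

    if var <= 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)

    if n <= EXACT_RANKSUM_MAX_N:
        total = comb(n, na)
        le = ge = 0
        for idx in combinations(range(n), na):
            ws = ranks[list(idx)].sum()
            if ws <= w + 1e-9:
                le += 1
            if ws >= w - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
    else:
        cc = 0.5 if abs(w - mu) > 0.5 else 0.0
        zc = (abs(w - mu) - cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(zc)))
    return float(z), float(p)


def auc(scores_pos, scores_neg) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) estimator.

    Equivalent to counting, over all (positive, negative) pairs, wins as 1 and
    ties as 1/2; equals the trapezoidal ROC area.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))
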