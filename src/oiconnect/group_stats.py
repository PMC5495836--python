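"""Group-level inferential statistics.

Group comparisons of connectivity measures use the two-sample Mann-Whitney
rank-sum test (exact enumeration for small tie-free samples, normal
approximation with tie correction otherwise), Benjamini-Hochberg FDR
adjustment across test families, Hedges' g effect sizes with the small-sample
bias correction, and Fisher's exact mid-P test for 2x2 association tables
(the sex-confound check).
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import EffectSize

__all__ = ["rank_sum_test", "bh_fdr", "hedges_g", "fisher_mid_p"]

#: Largest combined sample size for which the exact Mann-Whitney null
#: distribution is enumerated (matches the emulated study's group sizes).
EXACT_THRESHOLD = 12


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test; returns ``(p_value, U)``.

    The exact null distribution is used when the combined sample is small
    (<= 12) and tie-free; otherwise the normal approximation with tie
    correction and continuity correction is used.  U is reported for the
    first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= EXACT_THRESHOLD and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue), float(res.statistic)


def bh_fdr(p, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(rejected, p_adjusted)`` in the input order.  The adjusted
    p values are monotone: ``p_adj[(i)] = min_{j >= i} m p_(j) / j``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    # step-up: reject all p <= the largest p_(k) with p_(k) <= k q / m
    passing = np.nonzero(ranked <= np.arange(1, m + 1) * q / m)[0]
    k = passing.max() + 1 if passing.size else 0
    rejected_sorted = np.arange(m) < k
    rejected = np.empty(m, bool)
    rejected[order] = rejected_sorted
    p_adj = np.empty(m)
    p_adj[order] = adj
    return rejected, p_adj


def hedges_g(a, b) -> EffectSize:
    """Hedges' g standardized mean difference (a minus b).

    g = J * (mean_a - mean_b) / s_pooled with the small-sample correction
    J = 1 - 3 / (4 (n_a + n_b) - 9).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 + n2 < 3 or min(n1, n2) < 1:
        raise ValueError("need at least 3 observations in total")
    v1 = a.var(ddof=1) if n1 > 1 else 0.0
    v2 = b.var(ddof=1) if n2 > 1 else 0.0
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if pooled <= 0:
        raise ValueError("pooled variance is zero; effect size undefined")
    s = np.sqrt(pooled)
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return EffectSize(
        g=float(j * (a.mean() - b.mean()) / s), n1=n1, n2=n2, pooled_sd=float(s)
    )


def fisher_mid_p(table, alternative: str = "two-sided") -> float:
    """Fisher's exact mid-P test for a 2x2 contingency table.

    Under the hypergeometric null for the [0, 0] cell, the one-sided mid-P
    is the probability of a strictly more extreme table plus half the
    probability of the observed one.  ``alternative`` may be "greater",
    "less", or "two-sided" (twice the smaller one-sided mid-P, capped at 1).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    t = t.astype(int)
    if np.any(t < 0):
        raise ValueError("table entries must be nonnegative integers")
    x = t[0, 0]
    row1 = t[0].sum()
    col1 = t[:, 0].sum()
    total = t.sum()
    dist = stats.hypergeom(total, col1, row1)
    upper = dist.sf(x) + 0.5 * dist.pmf(x)
    lower = dist.cdf(x - 1) + 0.5 * dist.pmf(x)
    if alternative == "greater":
        return float(upper)
    if alternative == "less":
        return float(lower)
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * min(upper, lower)))
    raise ValueError("alternative must be 'greater', 'less', or 'two-sided'")
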