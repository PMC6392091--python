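"""Statistical primitives: Storey-Tibshirani q-values, rank-sum tests with
exact enumeration on small samples, and Holm step-down adjustment.

These are the inferential backbone of the screen: within-dataset
anticorrelation p-values and cluster-specificity rank-sum p-values are both
converted to q-values so that a cutoff of q <= 0.1 controls the false
discovery rate of the resulting call set.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .datatypes import ValidationError

#: enumeration budget for exact rank-sum p-values; C(16, 8) = 12870 so every
#: instance with both samples <= 8 is computed exactly.
EXACT_ENUM_LIMIT = 20_000


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def estimate_pi0(pvals: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 from a p-value vector.

    Uses the lambda-grid estimator pi0(lambda) = #{p > lambda} / (m (1-lambda))
    on lambda in {0.05, ..., 0.95}, smoothed with a cubic polynomial and
    extrapolated to lambda = 1, then clipped to (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 20:
        # too few p-values for a stable smoother; be conservative
        return 1.0
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coeffs, 1.0))
    return float(min(1.0, max(pi0, 1.0 / m)))


def estimate_qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey-Tibshirani q-values for a vector of p-values.

    With ``pi0=1`` the result is exactly the Benjamini-Hochberg step-up
    adjustment. ``pi0=None`` estimates pi0 from the data.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not (0 < pi0 <= 1):
        raise ValidationError(f"pi0 must be in (0, 1], got {pi0}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# rank-sum tests
# ---------------------------------------------------------------------------

def _exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact Mann-Whitney p by enumeration of all splits of the pooled sample.

    Ties are handled implicitly: the U statistic is recomputed for every
    split of the observed pooled values, so the permutation null is exact.
    """
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    total = len(pooled)

    def u_stat(xs: np.ndarray, ys: np.ndarray) -> float:
        # number of (x, y) pairs with x > y, ties counting 1/2
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_stat(np.asarray(x, float), np.asarray(y, float))
    mu = n * m / 2.0
    count = 0
    n_splits = 0
    idx = np.arange(total)
    for combo in combinations(idx, n):
        sel = np.zeros(total, dtype=bool)
        sel[list(combo)] = True
        u = u_stat(pooled[sel], pooled[~sel])
        n_splits += 1
        if alternative == "less":
            count += u <= u_obs + 1e-12
        elif alternative == "greater":
            count += u >= u_obs - 1e-12
        else:  # two-sided
            count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    return count / n_splits


def ranksum_test(x, y, alternative: str = "two-sided") -> float:
    """Mann-Whitney rank-sum p-value.

    ``alternative='less'`` tests x stochastically smaller than y. Exact
    enumeration is used whenever C(n+m, n) <= EXACT_ENUM_LIMIT (in
    particular for every instance with both samples <= 8); otherwise the
    normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("rank-sum test requires two non-empty samples")
    if comb(x.size + y.size, x.size) <= EXACT_ENUM_LIMIT:
        return float(_exact_ranksum_pvalue(x, y, alternative))
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic",
                           use_continuity=True)
    return float(res.pvalue)


def ks_test(x, y) -> float:
    """Two-sample Kolmogorov-Smirnov two-sided p (asymptotic distribution)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("KS test requires two non-empty samples")
    return float(sps.ks_2samp(x, y, method="asymp").pvalue)


# ---------------------------------------------------------------------------
# multiple testing: Holm step-down
# ---------------------------------------------------------------------------

def holm_adjust(pvals) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values.

    adjusted_(i) = min(1, max_{j<=i} (m-j+1) p_(j)) over p sorted ascending.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="mergesort")
    adj = np.maximum.accumulate((m - np.arange(m)) * p[order])
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
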