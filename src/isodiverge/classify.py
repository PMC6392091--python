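"""Dosage-like vs divergent classification of isozyme pairs.

A logistic model on the anticorrelation proportion p_m is fitted with
protein-complex pairs as the positive class and random pairs as the
negative class. An isozyme pair is then called "complex-like" when the
fitted odds P(C)/(1-P(C)) are at least the decision threshold (default 6,
matching the >= 6x resemblance criterion), "random-like" when the odds are
at most 1/threshold, and "ambiguous" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .datatypes import ValidationError
from .stats import ks_test, ranksum_test

#: L2 ridge strength capping the coefficients on separable data.
RIDGE_ALPHA = 1e-4


@dataclass
class PairClassifier:
    intercept: float
    slope: float
    odds_threshold: float = 6.0

    def predict_proba(self, p_m) -> np.ndarray:
        """P(complex-like) for anticorrelation proportions p_m."""
        eta = self.intercept + self.slope * np.asarray(p_m, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_classifier(
    complex_summaries: pd.DataFrame,
    random_summaries: pd.DataFrame,
    odds_threshold: float = 6.0,
) -> PairClassifier:
    """Fit the logistic model on p_m with complex=1, random=0.

    The fit is maximum likelihood up to a weak L2 ridge (strength 1e-4, the
    intercept unpenalized) so that coefficients stay finite and predicted
    probabilities stay inside (0, 1) even when the classes are perfectly
    separated, as is likely for small catalogs.
    """
    pc = np.asarray(complex_summaries["p_m"], dtype=float)
    pr = np.asarray(random_summaries["p_m"], dtype=float)
    if pc.size == 0 or pr.size == 0:
        raise ValidationError("both training classes must be non-empty")
    if np.any((pc < 0) | (pc > 1)) or np.any((pr < 0) | (pr > 1)):
        raise ValidationError("p_m values must lie in [0, 1]")
    X = np.concatenate([pc, pr])[:, None]
    y = np.concatenate([np.ones(pc.size), np.zeros(pr.size)])
    model = LogisticRegression(C=1.0 / RIDGE_ALPHA, solver="lbfgs", max_iter=10_000)
    model.fit(X, y)
    return PairClassifier(
        intercept=float(model.intercept_[0]),
        slope=float(model.coef_[0, 0]),
        odds_threshold=odds_threshold,
    )


def classify_pair(model: PairClassifier, p_m: float) -> tuple[float, str]:
    """(P(C), label) for one pair; thresholds are inclusive."""
    p = float(model.predict_proba([p_m])[0])
    odds = p / (1.0 - p)
    thr = model.odds_threshold
    tol = 1e-9  # inclusive boundaries up to float round-trip error
    if odds >= thr * (1 - tol):
        label = "complex-like"
    elif odds <= (1.0 / thr) * (1 + tol):
        label = "random-like"
    else:
        label = "ambiguous"
    return p, label


def classify_pairs(model: PairClassifier, summaries: pd.DataFrame) -> pd.DataFrame:
    """Classification table (pair_id, p_m, P_C, odds, label)."""
    rows = []
    for r in summaries.itertuples():
        p, label = classify_pair(model, r.p_m)
        rows.append((r.pair_id, r.p_m, p, p / (1.0 - p), label))
    return pd.DataFrame(rows, columns=["pair_id", "p_m", "P_C", "odds", "label"])


def compare_class_distributions(class_a, class_b, method: str = "ranksum") -> float:
    """Two-sided p-value comparing two p_m distributions.

    ``method='ranksum'`` (default, as in the class-level box-plot
    comparisons) uses the Mann-Whitney test: exact enumeration when both
    samples are small, otherwise the tie-corrected normal approximation.
    ``method='ks'`` uses the asymptotic two-sample Kolmogorov-Smirnov test.
    """
    a = np.asarray(class_a, dtype=float)
    b = np.asarray(class_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both classes must be non-empty")
    if method == "ranksum":
        return ranksum_test(a, b, alternative="two-sided")
    if method == "ks":
        return ks_test(a, b)
    raise ValidationError(f"unknown method {method!r}")
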