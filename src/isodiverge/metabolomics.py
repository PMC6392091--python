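"""Metabolomics normalization and mass-isotopomer correction.

Chemostat metabolite intensities are normalized by total cell volume,
log2-transformed, detrended against instrument run order with a
per-metabolite linear model y = a*x + b + eps (keeping the residuals eps),
and referenced to the mean residual of a chosen reference condition.
Mutant samples are compared to the wild-type sample run immediately
before. Mass-isotopomer distributions are corrected for natural 13C
abundance and 12C tracer impurity by ordinary least squares against a
forward correction matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .datatypes import ValidationError

NATURAL_13C = 0.011  # natural abundance of 13C per carbon
TRACER_12C_IMPURITY = 0.01  # ~1% 12C in nominally 13C-labeled tracer


@dataclass
class MetaboliteTable:
    """Metabolite x sample intensities plus per-sample metadata.

    ``samples`` must carry columns run_order (unique integers), strain,
    limitation, volume (total cell volume, > 0). ``values`` columns align
    with ``samples`` rows (sample ids).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    slopes: pd.Series | None = None
    intercepts: pd.Series | None = None
    state: tuple[str, ...] = ("raw",)

    def __post_init__(self) -> None:
        required = {"run_order", "strain", "limitation", "volume"}
        if not required.issubset(self.samples.columns):
            raise ValidationError(f"sample metadata needs columns {sorted(required)}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError("value columns must match sample metadata index")
        if self.samples["run_order"].duplicated().any():
            raise ValidationError("run orders must be unique")


def normalize_metabolite_table(
    table: MetaboliteTable, reference: dict[str, str]
) -> MetaboliteTable:
    """Volume-normalize, log2, detrend on run order, subtract reference.

    ``reference`` selects the reference samples by metadata equality,
    e.g. ``{"strain": "wt", "limitation": "glucose"}``; per-metabolite
    means of the reference residuals are subtracted at the end.
    """
    meta = table.samples
    if (meta["volume"] <= 0).any():
        raise ValidationError("total cell volumes must be positive")
    ref_mask = np.ones(len(meta), dtype=bool)
    for key, val in reference.items():
        ref_mask &= (meta[key] == val).to_numpy()
    if not ref_mask.any():
        raise ValidationError(f"reference selector {reference} matches no sample")

    vals = table.values.div(meta["volume"].to_numpy(), axis=1)
    vals = np.log2(vals)
    x = meta["run_order"].to_numpy(dtype=float)
    xc = x - x.mean()
    denom = (xc**2).sum()
    slopes = {}
    intercepts = {}
    resid = {}
    for met, row in vals.iterrows():
        y = row.to_numpy(dtype=float)
        a = float((xc * (y - y.mean())).sum() / denom) if denom > 0 else 0.0
        b = float(y.mean() - a * x.mean())
        eps = y - (a * x + b)
        slopes[met] = a
        intercepts[met] = b
        resid[met] = eps
    res = pd.DataFrame(resid, index=table.values.columns).T
    res = res.sub(res.loc[:, ref_mask].mean(axis=1), axis=0)
    return MetaboliteTable(
        values=res,
        samples=table.samples.copy(),
        slopes=pd.Series(slopes),
        intercepts=pd.Series(intercepts),
        state=("volume-normalized", "log2", "detrended", "referenced"),
    )


def paired_ratio(table: MetaboliteTable, wildtype: str = "wt") -> pd.DataFrame:
    """Mutant / wild-type ratios on the linear scale.

    Each non-wild-type sample is paired with the wild-type sample that was
    run immediately before it (by run order); the ratio per metabolite is
    2**(mutant - wt), the table values being on the log2 scale.
    """
    meta = table.samples.sort_values("run_order")
    wt_ids = [s for s in meta.index if meta.loc[s, "strain"] == wildtype]
    out = {}
    last_wt = None
    for s in meta.index:
        if meta.loc[s, "strain"] == wildtype:
            last_wt = s
            continue
        if last_wt is None:
            raise ValidationError(f"mutant sample {s} has no preceding wild-type sample")
        out[s] = np.power(2.0, table.values[s] - table.values[last_wt])
    if not wt_ids:
        raise ValidationError("no wild-type samples in table")
    return pd.DataFrame(out, index=table.values.index)


# ---------------------------------------------------------------------------
# mass-isotopomer correction
# ---------------------------------------------------------------------------

@dataclass
class IsotopeDistribution:
    """Mass-isotopomer fraction vector (M+0 .. M+n) for an n-carbon compound."""

    fractions: np.ndarray
    n_carbons: int
    nat_ab: float = NATURAL_13C
    tracer_impurity: float = TRACER_12C_IMPURITY
    correction_matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.size != self.n_carbons + 1:
            raise ValidationError(
                f"fraction vector length {self.fractions.size} != n_carbons+1 "
                f"({self.n_carbons + 1})"
            )
        if np.any(self.fractions < 0):
            raise ValidationError("isotopomer fractions must be non-negative")


def correction_matrix(
    n_carbons: int,
    nat_ab: float = NATURAL_13C,
    tracer_impurity: float = TRACER_12C_IMPURITY,
) -> np.ndarray:
    """Forward matrix A with A[:, j] the measured pattern of the j-labeled species.

    A species with j nominally labeled carbons contributes mass shifts from
    two independent binomials: each labeled carbon is 13C with probability
    1 - tracer_impurity, each unlabeled carbon is 13C at natural abundance.
    """
    n = n_carbons
    A = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        lab = binom.pmf(np.arange(j + 1), j, 1.0 - tracer_impurity)
        nat = binom.pmf(np.arange(n - j + 1), n - j, nat_ab)
        A[:, j] = np.convolve(lab, nat)  # length (j+1)+(n-j+1)-1 = n+1
    return A


def forward_simulate(
    labeled_fractions, n_carbons: int,
    nat_ab: float = NATURAL_13C, tracer_impurity: float = TRACER_12C_IMPURITY,
) -> IsotopeDistribution:
    """Measured pattern of a mixture of j-labeled species (convolution model)."""
    f = np.asarray(labeled_fractions, dtype=float)
    A = correction_matrix(n_carbons, nat_ab, tracer_impurity)
    return IsotopeDistribution(A @ f, n_carbons, nat_ab, tracer_impurity, A)


def correct_isotope_distribution(
    observed, n_carbons: int,
    nat_ab: float = NATURAL_13C, tracer_impurity: float = TRACER_12C_IMPURITY,
) -> IsotopeDistribution:
    """Least-squares correction of an observed mass-isotopomer pattern.

    Solves A f = observed for the true labeled-species fractions f, clips
    negatives to zero and renormalizes to sum 1.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size != n_carbons + 1:
        raise ValidationError(
            f"observed vector length {obs.size} != n_carbons+1 ({n_carbons + 1})"
        )
    if np.any(obs < 0):
        raise ValidationError("observed fractions must be non-negative")
    A = correction_matrix(n_carbons, nat_ab, tracer_impurity)
    f, *_ = np.linalg.lstsq(A, obs, rcond=None)
    f = np.clip(f, 0.0, None)
    total = f.sum()
    if total <= 0:
        raise ValidationError("correction produced an all-zero fraction vector")
    f = f / total
    return IsotopeDistribution(f, n_carbons, nat_ab, tracer_impurity, A)
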