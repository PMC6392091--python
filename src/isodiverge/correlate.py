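"""Per-dataset anticorrelation screening of gene pairs.

For a pair (x, y) and dataset d, the Pearson correlation r over the N
jointly observed arrays is Fisher-transformed,

    z = atanh(r) * sqrt(N - 3),

which is approximately standard normal under the null of no correlation.
The one-sided p-value for anticorrelation is the lower normal tail of z.
Within each pair class the p-values are converted to q-values and the
binary anticorrelation matrix B is thresholded at q <= q* (default 0.1)
with r < 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import norm

from .datatypes import ExpressionDataset, GenePair, ValidationError
from .stats import estimate_qvalues

log = logging.getLogger(__name__)

R_CLAMP = 1.0 - 1e-12  # keeps atanh finite on degenerate perfect correlations
P_FLOOR = 1e-300  # q-value machinery requires p > 0
MIN_JOINT = 6  # minimum jointly observed arrays for a retained record


@dataclass
class PairCorrelation:
    pair_id: str
    dataset_id: str
    r: float
    N: int
    z: float
    p_anti: float
    q: float | None = None


def fisher_z(r: float, n: int) -> float:
    """Fisher-transformed normalized correlation atanh(r) * sqrt(n-3)."""
    r = float(np.clip(r, -R_CLAMP, R_CLAMP))
    return float(np.arctanh(r) * np.sqrt(n - 3))


def pair_correlation(dataset: ExpressionDataset, pair: GenePair) -> PairCorrelation | None:
    """Correlation record for one pair in one dataset, or None if untestable.

    Untestable: a gene absent from the dataset, fewer than six jointly
    observed arrays, or zero variance in either gene over the joint arrays.
    """
    xa = dataset.gene_row(pair.gene_a)
    xb = dataset.gene_row(pair.gene_b)
    if xa is None or xb is None:
        return None
    joint = ~np.isnan(xa) & ~np.isnan(xb)
    n = int(joint.sum())
    if n < MIN_JOINT:
        log.debug("pair %s in %s skipped: N=%d < %d", pair.pair_id,
                  dataset.dataset_id, n, MIN_JOINT)
        return None
    a = xa[joint]
    b = xb[joint]
    if np.std(a) == 0 or np.std(b) == 0:
        log.debug("pair %s in %s skipped: zero variance", pair.pair_id,
                  dataset.dataset_id)
        return None
    r = float(np.corrcoef(a, b)[0, 1])
    z = fisher_z(r, n)
    p = float(norm.cdf(z))
    p = min(max(p, P_FLOOR), 1.0)
    return PairCorrelation(pair.pair_id, dataset.dataset_id, r, n, z, p)


def correlate_compendium(
    datasets: list[ExpressionDataset], pairs: list[GenePair]
) -> pd.DataFrame:
    """Correlation records for every pair x dataset, as a tidy table.

    Columns: pair_id, dataset_id, pair_class, r, N, z, p_anti. Untestable
    combinations are simply absent.
    """
    rows = []
    for pair in pairs:
        for ds in datasets:
            rec = pair_correlation(ds, pair)
            if rec is not None:
                rows.append(
                    (rec.pair_id, rec.dataset_id, pair.pair_class, rec.r,
                     rec.N, rec.z, rec.p_anti)
                )
    return pd.DataFrame(
        rows, columns=["pair_id", "dataset_id", "pair_class", "r", "N", "z", "p_anti"]
    )


def add_qvalues(
    records: pd.DataFrame, family: str = "per_class", pi0: float | None = None
) -> pd.DataFrame:
    """Attach FDR q-values to a correlation record table.

    ``family`` chooses the correction family: "per_class" (records of each
    pair class corrected together; the default, since class-specific
    anticorrelation rates are compared downstream), "global" (all records
    jointly), or "per_dataset". ``pi0=1.0`` forces the Benjamini-Hochberg
    adjustment.
    """
    if records.empty:
        out = records.copy()
        out["q"] = pd.Series(dtype=float)
        return out
    out = records.copy()
    if family == "global":
        out["q"] = estimate_qvalues(out["p_anti"].to_numpy(), pi0=pi0)
    elif family == "per_class":
        out["q"] = (
            out.groupby("pair_class", group_keys=False)["p_anti"]
            .transform(lambda p: estimate_qvalues(p.to_numpy(), pi0=pi0))
        )
    elif family == "per_dataset":
        out["q"] = (
            out.groupby("dataset_id", group_keys=False)["p_anti"]
            .transform(lambda p: estimate_qvalues(p.to_numpy(), pi0=pi0))
        )
    else:
        raise ValidationError(f"unknown q-value family {family!r}")
    return out


@dataclass
class AnticorrMatrix:
    """Binary pair x dataset anticorrelation matrix B at threshold q*."""

    frame: pd.DataFrame  # index pair_id, columns dataset_id, values 0/1
    q_star: float = 0.1

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


def build_B(
    records: pd.DataFrame,
    q_star: float = 0.1,
    pair_ids: list[str] | None = None,
    dataset_ids: list[str] | None = None,
) -> AnticorrMatrix:
    """Threshold q-annotated records into the binary matrix B.

    b[m, n] = 1 iff pair m has q <= q* and r < 0 in dataset n. Pair x
    dataset combinations without a record are 0. ``pair_ids`` /
    ``dataset_ids`` fix the row/column universe (pairs or datasets with no
    records at all then appear as all-zero rows/columns).
    """
    if "q" not in records.columns:
        raise ValidationError("records lack q-values; run add_qvalues first")
    if pair_ids is None:
        pair_ids = list(pd.unique(records["pair_id"]))
    if dataset_ids is None:
        dataset_ids = list(pd.unique(records["dataset_id"]))
    B = pd.DataFrame(0, index=pd.Index(pair_ids, name="pair_id"),
                     columns=pd.Index(dataset_ids, name="dataset_id"), dtype=int)
    hits = records[(records["q"] <= q_star) & (records["r"] < 0)]
    for pid, did in zip(hits["pair_id"], hits["dataset_id"]):
        if pid in B.index and did in B.columns:
            B.loc[pid, did] = 1
    return AnticorrMatrix(B, q_star=q_star)


def summarize_pairs(
    B: AnticorrMatrix, pair_classes: dict[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair anticorrelation proportions p_m and the dataset ranking.

    p_m = (sum_n b[m, n]) / n over all datasets in B. Datasets are ranked
    by column sum descending (most anticorrelated pairs first), ties broken
    lexicographically by dataset id.
    """
    n = B.frame.shape[1]
    p_m = B.frame.sum(axis=1) / max(n, 1)
    summaries = pd.DataFrame({"pair_id": B.frame.index, "p_m": p_m.to_numpy()})
    if pair_classes is not None:
        summaries["pair_class"] = summaries["pair_id"].map(pair_classes)
    col_sums = B.frame.sum(axis=0)
    ranking = (
        pd.DataFrame({"dataset_id": B.frame.columns, "n_anticorrelated": col_sums.to_numpy()})
        .sort_values(["n_anticorrelated", "dataset_id"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )
    return summaries, ranking


# ---------------------------------------------------------------------------
# PAM clustering of B rows
# ---------------------------------------------------------------------------

def _pam_objective(dist: np.ndarray, medoids: list[int]) -> float:
    return float(dist[:, medoids].min(axis=1).sum())


def pam_cluster_pairs(B: AnticorrMatrix, k: int, seed: int = 0) -> np.ndarray:
    """Partitioning-around-medoids labels for the binary rows of B.

    Manhattan distance (Hamming on 0/1 rows). Small instances (at most
    10000 candidate medoid sets) are solved exactly by enumeration;
    larger ones use the classical build + swap phases. Ties are broken by
    row index, so the result is deterministic; ``seed`` is accepted for
    interface symmetry but unused.
    """
    X = B.values.astype(float)
    n = X.shape[0]
    if k < 2 or k > n:
        raise ValidationError(f"k={k} must be in [2, {n}]")
    from math import comb as _comb

    if _comb(n, k) <= 10_000:
        labels, _ = pam_exhaustive(B, k)
        return labels
    dist = squareform(pdist(X, metric="cityblock")) if n > 1 else np.zeros((1, 1))

    # build phase: greedy medoid addition
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, None
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - dist[:, j], 0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)

    # swap phase
    improved = True
    while improved:
        improved = False
        obj = _pam_objective(dist, medoids)
        best = (obj, None, None)
        for mi, m in enumerate(medoids):
            for j in range(n):
                if j in medoids:
                    continue
                cand = medoids[:mi] + [j] + medoids[mi + 1:]
                o = _pam_objective(dist, cand)
                if o < best[0] - 1e-12:
                    best = (o, mi, j)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            improved = True

    labels = dist[:, sorted(medoids)].argmin(axis=1)
    return labels.astype(int)


def pam_exhaustive(B: AnticorrMatrix, k: int) -> tuple[np.ndarray, float]:
    """Globally optimal k-medoids by exhaustive search (small instances only)."""
    X = B.values.astype(float)
    n = X.shape[0]
    dist = squareform(pdist(X, metric="cityblock"))
    best_obj, best_medoids = np.inf, None
    for medoids in combinations(range(n), k):
        o = _pam_objective(dist, list(medoids))
        if o < best_obj - 1e-12:
            best_obj, best_medoids = o, medoids
    labels = dist[:, list(best_medoids)].argmin(axis=1)
    return labels.astype(int), float(best_obj)
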