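"""Grouping compendium datasets into perturbation clusters.

Similar experimental perturbations inflate the variance of similar genes,
so each dataset is summarized by its vector of per-gene standard
deviations. The gene x dataset variance matrix is imputed (KNN, 10
neighbors), log-transformed after a per-dataset offset of half the
smallest positive SD, column- then row-z-normalized, and clustered by
consensus k-means: 125 subsamples of 80% of genes and 80% of datasets are
each k-means clustered, the co-clustering frequencies form a consensus
matrix, and an average-linkage cut of 1 - consensus gives the final k
groups. The number of clusters is chosen by minimizing
AIC(k) = RSS(k) + 2*M*k, with M the gene-vector length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.impute import KNNImputer

from .datatypes import ExpressionDataset, ValidationError


@dataclass
class VarianceMatrix:
    frame: pd.DataFrame  # genes x datasets
    state: tuple[str, ...] = ("raw",)
    offsets: dict[str, float] = field(default_factory=dict)


@dataclass
class DatasetClustering:
    k: int
    labels: pd.Series  # dataset_id -> cluster label in 1..k
    consensus: pd.DataFrame
    rss: float
    M: int
    aic: float
    aic_curve: pd.DataFrame | None = None  # columns k, rss, aic

    def cluster_members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def variance_matrix(datasets: list[ExpressionDataset]) -> VarianceMatrix:
    """Per-gene sample standard deviations for every dataset (raw state).

    Entry (g, d) is the SD of gene g over its observed arrays in dataset d
    (ddof=1); genes observed fewer than twice in a dataset are missing.
    """
    all_genes: list[str] = []
    seen = set()
    for ds in datasets:
        for g in ds.gene_ids:
            if g not in seen:
                seen.add(g)
                all_genes.append(g)
    mat = pd.DataFrame(np.nan, index=all_genes,
                       columns=[ds.dataset_id for ds in datasets])
    for ds in datasets:
        vals = ds.values
        n_obs = (~np.isnan(vals)).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sds = np.nanstd(vals, axis=1, ddof=1)
        sds[n_obs < 2] = np.nan
        mat.loc[ds.gene_ids, ds.dataset_id] = sds
    return VarianceMatrix(mat, state=("raw",))


def preprocess_variance_matrix(
    vm: VarianceMatrix, missing_threshold: float = 0.7, knn_k: int = 10
) -> VarianceMatrix:
    """Impute, log, and doubly z-normalize a raw variance matrix.

    Steps, in order: (1) drop genes then datasets with more than
    ``missing_threshold`` missing entries; (2) KNN imputation with
    ``knn_k`` neighbor genes (Euclidean distance over co-observed
    entries, unweighted neighbor mean); (3) per-dataset offset of half the
    smallest positive SD, then natural log; (4) column z-normalization
    followed by row z-normalization (columns are deliberately left
    non-normalized afterward).
    """
    if "raw" not in vm.state or len(vm.state) > 1:
        raise ValidationError("preprocess_variance_matrix expects a raw matrix")
    df = vm.frame.copy()
    # (1) filter genes first, then datasets
    gene_missing = df.isna().mean(axis=1)
    df = df.loc[gene_missing <= missing_threshold]
    if df.empty:
        raise ValidationError("all genes exceed the missing-value threshold")
    ds_missing = df.isna().mean(axis=0)
    df = df.loc[:, ds_missing <= missing_threshold]
    if df.shape[1] == 0:
        raise ValidationError("all datasets exceed the missing-value threshold")
    # (2) KNN imputation over gene rows
    if df.isna().any().any():
        k = min(knn_k, max(1, df.shape[0] - 1))
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        imputed = imputer.fit_transform(df.to_numpy())
        df = pd.DataFrame(imputed, index=df.index, columns=df.columns)
    # (3) offset + log
    offsets = {}
    for col in df.columns:
        pos = df[col].to_numpy()
        pos = pos[pos > 0]
        offset = 0.5 * pos.min() if pos.size else 1e-12
        offsets[col] = float(offset)
        df[col] = np.log(df[col] + offset)
    # (4) column z-norm then row z-norm
    df = (df - df.mean(axis=0)) / df.std(axis=0, ddof=1).replace(0, 1.0)
    row_sd = df.std(axis=1, ddof=1).replace(0, 1.0)
    df = df.sub(df.mean(axis=1), axis=0).div(row_sd, axis=0)
    return VarianceMatrix(
        df, state=("logged", "column-normalized", "row-normalized"), offsets=offsets
    )


# ---------------------------------------------------------------------------
# k-means with greedy farthest-point initialization
# ---------------------------------------------------------------------------

def _farthest_point_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [X[rng.integers(X.shape[0])]]
    for _ in range(1, k):
        d2 = np.min(
            ((X[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(-1), axis=1
        )
        centers.append(X[int(np.argmax(d2))])
    return np.asarray(centers)


def _kmeans_once(X: np.ndarray, k: int, rng: np.random.Generator,
                 max_iter: int = 300) -> tuple[np.ndarray, float]:
    centers = _farthest_point_init(X, k, rng)
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new_labels = d2.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster on the farthest point
                centers[j] = X[int(np.argmax(d2.min(axis=1)))]
    inertia = float(((X - centers[labels]) ** 2).sum())
    return labels, inertia


def kmeans(X: np.ndarray, k: int, rng: np.random.Generator,
           n_restarts: int = 10, max_iter: int = 300) -> np.ndarray:
    """Best-of-``n_restarts`` Lloyd k-means with farthest-point init."""
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        labels, inertia = _kmeans_once(X, k, rng, max_iter=max_iter)
        if inertia < best_inertia - 1e-12:
            best_labels, best_inertia = labels, inertia
    return best_labels


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

def consensus_kmeans(
    vm: VarianceMatrix,
    k: int,
    n_subsamples: int = 125,
    fraction: float = 0.8,
    seed: int = 0,
) -> DatasetClustering:
    """Consensus k-means clustering of datasets for a fixed k.

    Subsamples ``fraction`` of genes and datasets ``n_subsamples`` times,
    k-means clusters the dataset columns of each subsample, accumulates
    the co-clustering frequency matrix, and cuts its average-linkage
    dendrogram (distance 1 - consensus) into k groups. RSS is the squared
    Euclidean distance of every full dataset vector to its final cluster
    centroid, and AIC = RSS + 2*M*k with M the number of genes.
    """
    df = vm.frame
    genes = df.index.to_numpy()
    ds_ids = df.columns.to_numpy()
    n_genes, n_ds = df.shape
    if k < 2 or k > n_ds:
        raise ValidationError(f"k={k} must be in [2, {n_ds}]")
    rng = np.random.default_rng(seed)
    X_full = df.to_numpy().T  # datasets x genes

    co = np.zeros((n_ds, n_ds))
    tried = np.zeros((n_ds, n_ds))
    n_sub_genes = max(1, int(round(fraction * n_genes)))
    n_sub_ds = max(k, int(round(fraction * n_ds)))
    for _ in range(n_subsamples):
        gi = rng.choice(n_genes, size=n_sub_genes, replace=False)
        di = rng.choice(n_ds, size=n_sub_ds, replace=False)
        X = X_full[np.ix_(di, gi)]
        labels = kmeans(X, k, rng)
        same = labels[:, None] == labels[None, :]
        tried[np.ix_(di, di)] += 1
        co[np.ix_(di, di)] += same
    with np.errstate(invalid="ignore"):
        consensus = np.where(tried > 0, co / np.maximum(tried, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = average(squareform(dist, checks=False))
    labels = fcluster(Z, t=k, criterion="maxclust")
    # fcluster can return fewer groups on degenerate trees; accept as-is
    rss = 0.0
    for c in np.unique(labels):
        members = X_full[labels == c]
        centroid = members.mean(axis=0)
        rss += float(((members - centroid) ** 2).sum())
    aic = rss + 2.0 * n_genes * k
    return DatasetClustering(
        k=k,
        labels=pd.Series(labels, index=pd.Index(ds_ids, name="dataset_id")),
        consensus=pd.DataFrame(consensus, index=ds_ids, columns=ds_ids),
        rss=rss,
        M=n_genes,
        aic=aic,
    )


def select_k_by_aic(
    vm: VarianceMatrix,
    k_range=range(2, 51),
    n_subsamples: int = 125,
    fraction: float = 0.8,
    seed: int = 0,
) -> DatasetClustering:
    """Run consensus k-means over ``k_range`` and return the AIC minimizer.

    Ties go to the smallest k. Each k uses an independent, seed-derived
    random stream so single-k runs are reproducible.
    """
    ks = [k for k in k_range if 2 <= k <= vm.frame.shape[1]]
    if not ks:
        raise ValidationError("k_range contains no feasible k")
    results = []
    for k in ks:
        res = consensus_kmeans(
            vm, k, n_subsamples=n_subsamples, fraction=fraction,
            seed=(seed * 100_003 + k) % (2**31 - 1)
        )
        results.append(res)
    curve = pd.DataFrame(
        {"k": ks, "rss": [r.rss for r in results], "aic": [r.aic for r in results]}
    )
    best = min(results, key=lambda r: (r.aic, r.k))
    best.aic_curve = curve
    return best
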