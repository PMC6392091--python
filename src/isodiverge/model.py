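"""Model/results interface over the divergence-screening pipeline.

``IsozymeDivergenceModel`` is constructed from a compendium of expression
datasets and a gene-pair catalog; ``fit()`` runs the full screen
(per-dataset anticorrelation, B matrix, pair summaries and classification,
dataset clustering by variance signature, cluster-specific association)
and returns an ``IsozymeDivergenceResults`` holding every intermediate
table plus a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as cio
from .associate import associate_all
from .classify import PairClassifier, classify_pairs, fit_classifier
from .cluster import (
    DatasetClustering,
    preprocess_variance_matrix,
    select_k_by_aic,
    variance_matrix,
)
from .correlate import (
    AnticorrMatrix,
    add_qvalues,
    build_B,
    correlate_compendium,
    summarize_pairs,
)
from .datatypes import ExpressionDataset, GenePair, ValidationError


@dataclass
class IsozymeDivergenceResults:
    """Fitted results: correlation records, B, clustering, associations."""

    records: pd.DataFrame
    B: AnticorrMatrix
    pair_summaries: pd.DataFrame
    dataset_ranking: pd.DataFrame
    clustering: DatasetClustering | None = None
    associations: pd.DataFrame | None = None
    classifier: PairClassifier | None = None
    classification: pd.DataFrame | None = None
    q_star: float = 0.1

    @property
    def associated_pairs(self) -> pd.DataFrame:
        if self.associations is None:
            return pd.DataFrame()
        return self.associations[self.associations["associated"]]

    def summary(self) -> str:
        lines = ["Isozyme divergence screen", "=" * 34]
        n_pairs = self.B.frame.shape[0]
        n_ds = self.B.frame.shape[1]
        lines.append(f"pairs screened:            {n_pairs}")
        lines.append(f"datasets:                  {n_ds}")
        lines.append(f"q* threshold:              {self.q_star}")
        lines.append(
            f"anticorrelation calls in B: {int(self.B.frame.to_numpy().sum())}"
        )
        if self.clustering is not None:
            lines.append(f"dataset clusters (AIC):    k={self.clustering.k}")
        if self.associations is not None:
            n_assoc = int(self.associations["associated"].sum())
            lines.append(f"associated pair x cluster: {n_assoc}")
            per_cluster = (
                self.associated_pairs.groupby("cluster_id")["pair_id"].count()
                if n_assoc
                else pd.Series(dtype=int)
            )
            for c, n in per_cluster.items():
                lines.append(f"  cluster {c}: {n} pairs")
        if self.classification is not None:
            counts = self.classification["label"].value_counts()
            lines.append("pair classification: " + ", ".join(
                f"{lab}={int(n)}" for lab, n in counts.items()
            ))
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_results(self.records, out / "records.tsv")
        cio.write_results(self.B.frame, out / "B.tsv", index=True)
        cio.write_results(self.pair_summaries, out / "pair_summaries.tsv")
        cio.write_results(self.dataset_ranking, out / "dataset_ranking.tsv")
        if self.clustering is not None:
            labels = self.clustering.labels.rename("cluster").reset_index()
            cio.write_results(labels, out / "dataset_clusters.tsv")
            cio.write_results(self.clustering.consensus, out / "consensus.tsv",
                              index=True)
            if self.clustering.aic_curve is not None:
                cio.write_results(self.clustering.aic_curve, out / "aic_curve.tsv")
        if self.associations is not None:
            cio.write_results(self.associations, out / "associations.tsv")
        if self.classification is not None:
            cio.write_results(self.classification, out / "classification.tsv")


class IsozymeDivergenceModel:
    """Condition-specific expression-divergence screen for gene pairs.

    Parameters
    ----------
    datasets : list of ExpressionDataset
        The compendium; every dataset needs at least six arrays.
    pairs : list of GenePair
        Catalog of pairs labeled isozyme / complex / pathway / random.
    q_star : float
        FDR threshold for anticorrelation calls and cluster association.
    q_family : str
        Correction family for the B matrix ("per_class", "global",
        "per_dataset").
    """

    def __init__(
        self,
        datasets: list[ExpressionDataset],
        pairs: list[GenePair],
        q_star: float = 0.1,
        q_family: str = "per_class",
        odds_threshold: float = 6.0,
    ) -> None:
        if not datasets:
            raise ValidationError("compendium is empty")
        if not pairs:
            raise ValidationError("pair catalog is empty")
        self.datasets = datasets
        self.pairs = pairs
        self.q_star = q_star
        self.q_family = q_family
        self.odds_threshold = odds_threshold

    @classmethod
    def from_manifest(cls, manifest_path, pairs_path, **kwargs) -> "IsozymeDivergenceModel":
        datasets = cio.load_compendium(manifest_path)
        pairs = cio.load_pair_catalog(pairs_path)
        return cls(datasets, pairs, **kwargs)

    def fit(
        self,
        k_range=range(2, 9),
        n_subsamples: int = 125,
        subsample_fraction: float = 0.8,
        knn_k: int = 10,
        missing_threshold: float = 0.7,
        cluster: bool = True,
        seed: int = 0,
        pi0: float | None = None,
    ) -> IsozymeDivergenceResults:
        records = correlate_compendium(self.datasets, self.pairs)
        records = add_qvalues(records, family=self.q_family, pi0=pi0)
        all_ds = [d.dataset_id for d in self.datasets]
        all_pairs = [p.pair_id for p in self.pairs]
        B = build_B(records, q_star=self.q_star, pair_ids=all_pairs,
                    dataset_ids=all_ds)
        classes = {p.pair_id: p.pair_class for p in self.pairs}
        summaries, ranking = summarize_pairs(B, pair_classes=classes)

        classifier = None
        classification = None
        cx = summaries[summaries["pair_class"] == "complex"]
        rd = summaries[summaries["pair_class"] == "random"]
        if len(cx) >= 2 and len(rd) >= 2:
            classifier = fit_classifier(cx, rd, odds_threshold=self.odds_threshold)
            iso = summaries[summaries["pair_class"] == "isozyme"]
            target = iso if len(iso) else summaries
            classification = classify_pairs(classifier, target)

        clustering = None
        associations = None
        if cluster and len(self.datasets) >= 2:
            vm = variance_matrix(self.datasets)
            vm = preprocess_variance_matrix(vm, missing_threshold=missing_threshold,
                                            knn_k=knn_k)
            clustering = select_k_by_aic(
                vm, k_range=k_range, n_subsamples=n_subsamples,
                fraction=subsample_fraction, seed=seed,
            )
            associations = associate_all(records, clustering, pair_ids=all_pairs,
                                         q_star=self.q_star)
        return IsozymeDivergenceResults(
            records=records,
            B=B,
            pair_summaries=summaries,
            dataset_ranking=ranking,
            clustering=clustering,
            associations=associations,
            classifier=classifier,
            classification=classification,
            q_star=self.q_star,
        )
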