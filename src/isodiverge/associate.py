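"""Associating gene pairs with dataset clusters.

A pair is associated with a cluster C when two criteria hold:

1. The mean normalized correlation inside the cluster is negative,
   (1/|C|) * sum_{d in C} atanh(r_d) * sqrt(N_d - 3) < 0 (strict).
2. The normalized correlations z inside C are stochastically smaller than
   those outside (one-tailed rank-sum test), with the resulting p-values
   corrected to q-values over the full family of tested pair x cluster
   combinations and thresholded at q <= 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import DatasetClustering
from .stats import estimate_qvalues, ranksum_test

log = logging.getLogger(__name__)

#: minimum record counts for a testable pair x cluster combination
MIN_IN, MIN_OUT = 1, 3


@dataclass
class AssociationResult:
    pair_id: str
    cluster_id: int
    mean_z_in: float
    n_in: int
    n_out: int
    ranksum_p: float
    q: float | None = None
    associated: bool | None = None


def associate_pair_cluster(
    records: pd.DataFrame, clustering: DatasetClustering, cluster_id: int
) -> AssociationResult | None:
    """Two-criterion statistics for one pair against one cluster.

    ``records`` holds all correlation records of a single pair. Returns
    None (untested) when the pair has fewer than 1 in-cluster or 3
    out-of-cluster records.
    """
    members = set(clustering.cluster_members(cluster_id))
    in_mask = records["dataset_id"].isin(members)
    z_in = records.loc[in_mask, "z"].to_numpy()
    z_out = records.loc[~in_mask, "z"].to_numpy()
    if z_in.size < MIN_IN or z_out.size < MIN_OUT:
        log.debug("pair %s x cluster %s untested (n_in=%d, n_out=%d)",
                  records["pair_id"].iloc[0] if len(records) else "?",
                  cluster_id, z_in.size, z_out.size)
        return None
    mean_z_in = float(z_in.mean())
    p = ranksum_test(z_in, z_out, alternative="less")
    return AssociationResult(
        pair_id=str(records["pair_id"].iloc[0]),
        cluster_id=int(cluster_id),
        mean_z_in=mean_z_in,
        n_in=int(z_in.size),
        n_out=int(z_out.size),
        ranksum_p=float(p),
    )


def associate_all(
    records: pd.DataFrame,
    clustering: DatasetClustering,
    pair_ids: list[str] | None = None,
    q_star: float = 0.1,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Association table over every testable pair x cluster combination.

    q-values are computed over the full family of tested combinations
    (criterion-1 failures included in the family; criterion 1 is applied
    only in the final ``associated`` flag). Output is sorted by
    (cluster_id, q).
    """
    if pair_ids is None:
        pair_ids = list(pd.unique(records["pair_id"]))
    clusters = sorted(np.unique(clustering.labels.to_numpy()))
    rows: list[AssociationResult] = []
    grouped = dict(tuple(records.groupby("pair_id")))
    for pid in pair_ids:
        recs = grouped.get(pid)
        if recs is None or recs.empty:
            continue
        for c in clusters:
            res = associate_pair_cluster(recs, clustering, c)
            if res is not None:
                rows.append(res)
    if not rows:
        return pd.DataFrame(
            columns=["pair_id", "cluster_id", "mean_z_in", "n_in", "n_out",
                     "ranksum_p", "q", "associated"]
        )
    out = pd.DataFrame(
        [
            (r.pair_id, r.cluster_id, r.mean_z_in, r.n_in, r.n_out, r.ranksum_p)
            for r in rows
        ],
        columns=["pair_id", "cluster_id", "mean_z_in", "n_in", "n_out", "ranksum_p"],
    )
    out["q"] = estimate_qvalues(out["ranksum_p"].clip(lower=1e-300).to_numpy(), pi0=pi0)
    out["associated"] = (out["mean_z_in"] < 0) & (out["q"] <= q_star)
    return out.sort_values(["cluster_id", "q"], kind="mergesort").reset_index(drop=True)
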