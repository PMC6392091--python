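"""Anticorrelation screening: Fisher z, B matrix, summaries, PAM."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from isodiverge import (
    AnticorrMatrix,
    ExpressionDataset,
    GenePair,
    ValidationError,
    add_qvalues,
    build_B,
    correlate_compendium,
    fisher_z,
    pair_correlation,
    pam_cluster_pairs,
    summarize_pairs,
)
from isodiverge.correlate import pam_exhaustive


def _dataset(values, dataset_id="D0", genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    arrays = [f"a{j}" for j in range(values.shape[1])]
    return ExpressionDataset(dataset_id, genes, arrays, values)


# ---------------------------------------------------------------------------
# Fisher z and per-pair records
# ---------------------------------------------------------------------------

def test_fisher_z_matches_log_form_on_grid():
    # z = 0.5 ln((1+r)/(1-r)) * sqrt(N-3), checked to 1e-10
    for r in np.linspace(-0.99, 0.99, 41):
        for n in (6, 7, 12, 50, 400):
            expected = 0.5 * np.log((1 + r) / (1 - r)) * np.sqrt(n - 3)
            assert fisher_z(r, n) == pytest.approx(expected, abs=1e-10)


def test_fisher_z_known_values():
    assert fisher_z(0.0, 10) == 0.0
    assert fisher_z(0.5, 12) == pytest.approx(np.arctanh(0.5) * 3, abs=1e-12)
    assert fisher_z(-0.9, 7) == pytest.approx(-2.94443898, abs=1e-6)


def test_fisher_z_finite_at_perfect_correlation():
    assert np.isfinite(fisher_z(1.0, 10))
    assert np.isfinite(fisher_z(-1.0, 10))


def test_pair_correlation_record():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20)
    ds = _dataset(np.vstack([x, -x + 0.1 * rng.normal(size=20)]), genes=["ga", "gb"])
    rec = pair_correlation(ds, GenePair("P", "ga", "gb", "isozyme"))
    assert rec.N == 20
    assert rec.r < -0.9
    assert rec.z == pytest.approx(fisher_z(rec.r, 20))
    assert rec.p_anti == pytest.approx(norm.cdf(rec.z))
    assert np.sign(rec.z) == np.sign(rec.r)


def test_pair_correlation_skips_degenerate_cases():
    rng = np.random.default_rng(1)
    pair = GenePair("P", "ga", "gb", "isozyme")
    # zero variance
    ds = _dataset(np.vstack([np.ones(8), rng.normal(size=8)]), genes=["ga", "gb"])
    assert pair_correlation(ds, pair) is None
    # too few joint observations
    vals = rng.normal(size=(2, 8))
    vals[0, :3] = np.nan
    vals[1, 3:6] = np.nan
    ds = _dataset(vals, genes=["ga", "gb"])
    assert pair_correlation(ds, pair) is None
    # missing gene
    ds = _dataset(rng.normal(size=(1, 8)), genes=["ga"])
    assert pair_correlation(ds, pair) is None


def test_z_invariant_to_affine_rescaling():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(2, 15))
    pair = GenePair("P", "ga", "gb", "isozyme")
    rec = pair_correlation(_dataset(base, genes=["ga", "gb"]), pair)
    scaled = np.vstack([3.0 * base[0] - 7.0, 0.2 * base[1] + 4.0])
    rec2 = pair_correlation(_dataset(scaled, genes=["ga", "gb"]), pair)
    assert rec2.z == pytest.approx(rec.z, abs=1e-10)


# ---------------------------------------------------------------------------
# B matrix and summaries
# ---------------------------------------------------------------------------

def _record_row(pair_id, dataset_id, r, q):
    return {
        "pair_id": pair_id, "dataset_id": dataset_id, "pair_class": "isozyme",
        "r": r, "N": 10, "z": fisher_z(r, 10), "p_anti": 0.5, "q": q,
    }


def test_build_B_thresholding():
    records = pd.DataFrame([
        _record_row("P0", "D0", -0.5, 0.1),   # inclusive at q = q*
        _record_row("P0", "D1", 0.5, 0.05),   # positive r never called
        _record_row("P1", "D0", -0.5, 0.2),   # q above threshold
    ])
    B = build_B(records, q_star=0.1, pair_ids=["P0", "P1", "P2"],
                dataset_ids=["D0", "D1"])
    assert B.frame.loc["P0", "D0"] == 1
    assert B.frame.loc["P0", "D1"] == 0
    assert B.frame.loc["P1", "D0"] == 0
    assert (B.frame.loc["P2"] == 0).all()  # no records -> all-zero row


def test_build_B_requires_qvalues():
    records = pd.DataFrame([_record_row("P0", "D0", -0.5, 0.1)]).drop(columns="q")
    with pytest.raises(ValidationError):
        build_B(records)


def test_add_qvalues_families():
    rng = np.random.default_rng(3)
    records = pd.DataFrame({
        "pair_id": [f"P{i}" for i in range(40)],
        "dataset_id": ["D0", "D1"] * 20,
        "pair_class": ["isozyme"] * 20 + ["random"] * 20,
        "r": rng.uniform(-1, 1, size=40),
        "N": 10, "z": 0.0,
        "p_anti": rng.uniform(1e-3, 1, size=40),
    })
    per_class = add_qvalues(records, family="per_class", pi0=1.0)
    glob = add_qvalues(records, family="global", pi0=1.0)
    assert set(per_class.columns) == set(glob.columns)
    # per-class correction is independent across classes
    iso = records[records.pair_class == "isozyme"]
    from isodiverge import estimate_qvalues
    np.testing.assert_allclose(
        per_class.loc[iso.index, "q"],
        estimate_qvalues(iso.p_anti.to_numpy(), pi0=1.0),
    )
    with pytest.raises(ValidationError):
        add_qvalues(records, family="per_experiment")


def test_summarize_pairs_and_ranking():
    frame = pd.DataFrame(
        [[1, 0, 1], [1, 1, 1], [0, 0, 0]],
        index=["P0", "P1", "P2"], columns=["D2", "D1", "D3"],
    )
    B = AnticorrMatrix(frame)
    summaries, ranking = summarize_pairs(B)
    assert dict(zip(summaries.pair_id, summaries.p_m)) == {
        "P0": pytest.approx(2 / 3), "P1": 1.0, "P2": 0.0
    }
    # column sums: D2=2, D1=1, D3=2 -> ties broken lexicographically
    assert list(ranking.dataset_id) == ["D2", "D3", "D1"]


def test_summarize_all_zero_matrix_stable():
    frame = pd.DataFrame(0, index=["P0", "P1"], columns=["D1", "D0"])
    summaries, ranking = summarize_pairs(AnticorrMatrix(frame))
    assert (summaries.p_m == 0).all()
    assert list(ranking.dataset_id) == ["D0", "D1"]


# ---------------------------------------------------------------------------
# PAM
# ---------------------------------------------------------------------------

def _bmat(rows):
    arr = np.asarray(rows)
    frame = pd.DataFrame(arr, index=[f"P{i}" for i in range(arr.shape[0])],
                         columns=[f"D{j}" for j in range(arr.shape[1])])
    return AnticorrMatrix(frame)


def test_pam_identical_rows_cocluster():
    B = _bmat([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
    labels = pam_cluster_pairs(B, k=2)
    assert labels[0] == labels[1] != labels[2]


def test_pam_k_equals_distinct_rows_gives_zero_objective():
    B = _bmat([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
    _, obj = pam_exhaustive(B, 3)
    assert obj == 0.0
    labels = pam_cluster_pairs(B, k=3)
    assert len(set(labels)) == 3


def test_pam_recovers_planted_hamming_groups():
    rows = [
        [1, 1, 1, 0, 0, 0, 0, 0, 0],
        [1, 1, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 1, 1, 1, 0, 0, 0],
        [0, 0, 0, 1, 1, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 1, 1, 1],
        [0, 0, 0, 0, 0, 0, 1, 1, 0],
    ]
    B = _bmat(rows)
    labels = pam_cluster_pairs(B, k=3)
    truth = [0, 0, 1, 1, 2, 2]
    groups = {}
    for lab, t in zip(labels, truth):
        groups.setdefault(t, set()).add(lab)
    assert all(len(g) == 1 for g in groups.values())
    assert len({next(iter(g)) for g in groups.values()}) == 3


def test_pam_matches_exhaustive_optimum_on_small_instances():
    rng = np.random.default_rng(17)
    from scipy.spatial.distance import pdist, squareform

    for trial in range(10):
        n = int(rng.integers(4, 9))
        B = _bmat(rng.integers(0, 2, size=(n, 6)))
        for k in (2, 3):
            labels = pam_cluster_pairs(B, k=k)
            _, best_obj = pam_exhaustive(B, k)
            # k-medoids objective induced by the heuristic's partition:
            # per cluster, the best member medoid's summed distance
            dist = squareform(pdist(B.values.astype(float), metric="cityblock"))
            total = 0.0
            for c in set(labels):
                members = np.where(labels == c)[0]
                sub = dist[np.ix_(members, members)]
                total += sub.sum(axis=0).min()
            assert total == pytest.approx(best_obj, abs=1e-9)


def test_pam_validates_k():
    B = _bmat([[1, 0], [0, 1]])
    with pytest.raises(ValidationError):
        pam_cluster_pairs(B, k=5)


# ---------------------------------------------------------------------------
# class-level screen behavior
# ---------------------------------------------------------------------------

def test_correlate_compendium_columns(default_compendium):
    datasets, pairs, _ = default_compendium
    records = correlate_compendium(datasets[:2], pairs[:5])
    assert list(records.columns) == [
        "pair_id", "dataset_id", "pair_class", "r", "N", "z", "p_anti"
    ]
    assert records.p_anti.between(0, 1, inclusive="right").all()
    assert (records.N >= 6).all()
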