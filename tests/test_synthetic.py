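"""Generator determinism, planted-signal calibration, fixtures."""

import numpy as np
import pytest

from isodiverge import (
    SyntheticConfig,
    SyntheticTruth,
    ValidationError,
    generate_compendium,
    generate_fixtures,
    generate_metabolomics_fixture,
    write_compendium,
)


def test_config_validation():
    with pytest.raises(ValidationError):
        SyntheticConfig(arrays_range=(4, 10))  # below the 6-array minimum
    with pytest.raises(ValidationError):
        SyntheticConfig(n_genes=10)  # pair demand exceeds gene supply
    with pytest.raises(ValidationError):
        SyntheticConfig(missing_rate=1.0)
    with pytest.raises(ValidationError):
        SyntheticConfig(signature_variance_multiplier=1.0)


def test_same_seed_reproduces_byte_identical_outputs(tmp_path):
    cfg = SyntheticConfig(seed=5, n_genes=60, n_clusters=2,
                          datasets_per_cluster=2, n_divergent_pairs_per_cluster=2,
                          n_coexpressed_pairs=2, n_random_pairs=2,
                          signature_genes_per_cluster=5)
    for run in ("one", "two"):
        datasets, pairs, truth = generate_compendium(cfg)
        write_compendium(datasets, pairs, truth, tmp_path / run)
    for name in ["manifest.tsv", "pairs.tsv", "truth.json", "D000.pcl", "D003.pcl"]:
        assert (tmp_path / "one" / name).read_bytes() == \
            (tmp_path / "two" / name).read_bytes()


def test_missing_rate_zero_leaves_no_masked_entries():
    cfg = SyntheticConfig(seed=1, missing_rate=0.0)
    datasets, _, _ = generate_compendium(cfg)
    assert not any(np.isnan(ds.values).any() for ds in datasets)


def test_truth_structure(default_compendium):
    datasets, pairs, truth = default_compendium
    assert set(truth.dataset_cluster) == {ds.dataset_id for ds in datasets}
    assert set(truth.pair_class) == {p.pair_id for p in pairs}
    assert set(truth.target_cluster) == {
        p for p, c in truth.pair_class.items() if c == "divergent"
    }
    assert set(truth.target_cluster.values()) <= set(truth.dataset_cluster.values())
    # catalog labels mirror planted classes
    for p in pairs:
        expected = {"divergent": "isozyme", "coexpressed": "complex",
                    "random": "random"}[truth.pair_class[p.pair_id]]
        assert p.pair_class == expected


def test_truth_json_roundtrip(tmp_path, default_compendium):
    _, _, truth = default_compendium
    truth.to_json(tmp_path / "truth.json")
    back = SyntheticTruth.from_json(tmp_path / "truth.json")
    assert back == truth


def test_planted_divergent_correlation_matches_closed_form():
    # pooled within-target-cluster correlation vs -beta^2/(beta^2+1),
    # >= 1000 pooled arrays, tolerance 0.05
    cfg = SyntheticConfig(
        seed=2, n_clusters=2, datasets_per_cluster=2, arrays_range=(500, 500),
        n_divergent_pairs_per_cluster=2, n_coexpressed_pairs=1, n_random_pairs=1,
        n_genes=40, signature_genes_per_cluster=2, missing_rate=0.0,
    )
    datasets, pairs, truth = generate_compendium(cfg)
    expected = cfg.expected_divergent_r
    assert expected == pytest.approx(-0.6923, abs=1e-4)
    for pid, target in truth.target_cluster.items():
        pair = next(p for p in pairs if p.pair_id == pid)
        xs, ys = [], []
        for ds in datasets:
            if truth.dataset_cluster[ds.dataset_id] != target:
                continue
            xs.append(ds.gene_row(pair.gene_a))
            ys.append(ds.gene_row(pair.gene_b))
        r = np.corrcoef(np.concatenate(xs), np.concatenate(ys))[0, 1]
        assert r == pytest.approx(expected, abs=0.05)


def test_divergent_pairs_uncorrelated_outside_target_cluster():
    cfg = SyntheticConfig(seed=3, arrays_range=(200, 200), missing_rate=0.0)
    datasets, pairs, truth = generate_compendium(cfg)
    pid, target = next(iter(truth.target_cluster.items()))
    pair = next(p for p in pairs if p.pair_id == pid)
    xs, ys = [], []
    for ds in datasets:
        if truth.dataset_cluster[ds.dataset_id] == target:
            continue
        xs.append(ds.gene_row(pair.gene_a))
        ys.append(ds.gene_row(pair.gene_b))
    r = np.corrcoef(np.concatenate(xs), np.concatenate(ys))[0, 1]
    assert abs(r) < 0.1


def test_null_config_has_exchangeable_correlations():
    # with nothing planted, random-pair correlations look like background
    cfg = SyntheticConfig(
        seed=4, n_divergent_pairs_per_cluster=0, n_coexpressed_pairs=0,
        n_random_pairs=10, random_pair_loading=0.0, missing_rate=0.0,
    )
    datasets, pairs, _ = generate_compendium(cfg)
    rng = np.random.default_rng(0)
    rs_pairs, rs_background = [], []
    for ds in datasets[:6]:
        for p in pairs:
            a, b = ds.gene_row(p.gene_a), ds.gene_row(p.gene_b)
            rs_pairs.append(np.corrcoef(a, b)[0, 1])
        for _ in range(10):
            i, j = rng.choice(len(ds.gene_ids), size=2, replace=False)
            rs_background.append(np.corrcoef(ds.values[i], ds.values[j])[0, 1])
    from scipy.stats import ks_2samp

    assert ks_2samp(rs_pairs, rs_background).pvalue > 0.01


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def test_catalog_fixture_composition(fixture_catalog):
    candidates, _ = fixture_catalog
    genuine = [c for c in candidates if not c.pair_id.startswith("DEC")]
    assert len(genuine) == 77
    fail_v = [c for c in genuine if not c.proteins_same_compartment]
    assert len(fail_v) == 24
    assert all(
        c.same_reaction and c.small_molecule_substrates and c.same_cofactor
        and c.reaction_same_compartment
        for c in genuine
    )
    decoys = [c for c in candidates if c.pair_id.startswith("DEC")]
    assert decoys and all(
        not (c.same_reaction and c.small_molecule_substrates and c.same_cofactor
             and c.reaction_same_compartment)
        for c in decoys
    )


def test_pathway_fixture_counts(fixture_catalog):
    _, table = fixture_catalog
    assert table.n_reactions == 632
    assert table.n_isozyme == 51
    glyc = table.frame[table.frame.category == "glycolysis_gluconeogenesis_fermentation"]
    assert len(glyc) == 12
    assert int(glyc.isozyme_flag.sum()) == 8


def test_fixtures_deterministic(fixture_catalog):
    c2, t2 = generate_fixtures()
    assert c2 == fixture_catalog[0]
    assert t2.frame.equals(fixture_catalog[1].frame)


# ---------------------------------------------------------------------------
# metabolomics fixture
# ---------------------------------------------------------------------------

def test_metabolomics_fixture_deterministic():
    f1 = generate_metabolomics_fixture(seed=7)
    f2 = generate_metabolomics_fixture(seed=7)
    assert f1.table.values.equals(f2.table.values)
    assert f1.table.samples.equals(f2.table.samples)


def test_metabolomics_fixture_zero_drift_is_flat():
    fx = generate_metabolomics_fixture(seed=1, drift_slope=0.0)
    vals = np.log2(fx.table.values.to_numpy()
                   / fx.table.samples["volume"].to_numpy()[None, :])
    # without drift, wild-type log2 levels are constant per metabolite
    wt = (fx.table.samples["strain"] == "wt").to_numpy()
    np.testing.assert_allclose(vals[:, wt].std(axis=1), 0.0, atol=1e-9)


def test_metabolomics_fixture_isotopes_match_direct_convolution():
    fx = generate_metabolomics_fixture(seed=2)
    from numpy.polynomial import polynomial as P

    for true_frac, obs in fx.isotopes:
        n = obs.n_carbons
        # direct polynomial convolution oracle
        pattern = np.zeros(n + 1)
        for j, fj in enumerate(true_frac):
            poly = np.array([1.0])
            for _ in range(j):  # labeled carbons: 12C at impurity rate
                poly = P.polymul(poly, [obs.tracer_impurity, 1 - obs.tracer_impurity])
            for _ in range(n - j):  # unlabeled carbons: 13C at natural abundance
                poly = P.polymul(poly, [1 - obs.nat_ab, obs.nat_ab])
            pattern[: poly.size] += fj * poly
        np.testing.assert_allclose(obs.fractions, pattern, atol=1e-12)
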