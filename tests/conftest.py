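import collections

import numpy as np
import pandas as pd
import pytest

from isodiverge import (
    IsozymeDivergenceModel,
    SyntheticConfig,
    generate_compendium,
    generate_fixtures,
)


@pytest.fixture(scope="session")
def default_compendium():
    """One default synthetic compendium (datasets, pairs, truth)."""
    return generate_compendium(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_fit(default_compendium):
    """Full model fit on the default compendium, shared across tests."""
    datasets, pairs, truth = default_compendium
    model = IsozymeDivergenceModel(datasets, pairs)
    return model.fit(seed=0), truth


@pytest.fixture(scope="session")
def fixture_catalog():
    return generate_fixtures()


def majority_cluster_map(labels: pd.Series, truth) -> dict:
    """Map each true cluster id to the majority predicted label."""
    out = {}
    for c in set(truth.dataset_cluster.values()):
        members = [d for d in labels.index if truth.dataset_cluster[d] == c]
        out[c] = collections.Counter(labels[members]).most_common(1)[0][0]
    return out


def make_records(z_in, z_out, in_ids=None, out_ids=None, pair_id="P0"):
    """Correlation-record table for one pair from explicit z values."""
    z_in = list(z_in)
    z_out = list(z_out)
    if in_ids is None:
        in_ids = [f"DI{i}" for i in range(len(z_in))]
    if out_ids is None:
        out_ids = [f"DO{i}" for i in range(len(z_out))]
    rows = []
    for did, z in zip(list(in_ids) + list(out_ids), z_in + z_out):
        r = np.tanh(z / np.sqrt(10 - 3))
        rows.append((pair_id, did, "isozyme", r, 10, z, 0.5))
    return pd.DataFrame(
        rows, columns=["pair_id", "dataset_id", "pair_class", "r", "N", "z", "p_anti"]
    )
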