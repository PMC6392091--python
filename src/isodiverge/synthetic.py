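"""Synthetic compendia, catalogs, and metabolomics inputs with known truth.

The generator emulates the statistical structure of a real expression
compendium at desk scale:

* several datasets of Gaussian log-expression, grouped into perturbation
  clusters of equal size;
* a minority of "coexpressed" pairs sharing a positive latent factor in
  every dataset (dosage-like behavior, the protein-complex analog);
* a majority of "divergent" pairs loading with opposite signs on a shared
  per-array factor, but only inside the datasets of one target cluster —
  condition-specific anticorrelation;
* "random" pairs carrying a weaker shared factor whose loading signs are
  re-drawn independently per dataset, so they are sometimes correlated and
  sometimes anticorrelated with no cluster alignment. This mirrors the
  empirical ordering in real compendia, where random gene pairs show more
  background anticorrelation than co-complexed pairs. Setting
  ``random_pair_loading=0`` makes them pure noise (the null configuration);
* per-cluster signature genes whose noise SD is inflated inside their
  cluster's datasets, giving each cluster a variance fingerprint;
* completely-at-random missing values.

A divergent pair with loading beta on a unit factor and unit noise has
within-target-cluster correlation -beta^2 / (beta^2 + 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CompendiumManifest,
    ExpressionDataset,
    GenePair,
    IsozymeCandidate,
    ManifestEntry,
    PathwayTable,
    ValidationError,
)
from . import io as cio
from .metabolomics import (
    IsotopeDistribution,
    MetaboliteTable,
    forward_simulate,
)


@dataclass
class SyntheticConfig:
    n_genes: int = 180
    n_clusters: int = 4
    datasets_per_cluster: int = 6
    arrays_range: tuple[int, int] = (12, 24)
    n_divergent_pairs_per_cluster: int = 5
    n_coexpressed_pairs: int = 10
    n_random_pairs: int = 20
    factor_loading: float = 1.5
    noise_sd: float = 1.0
    signature_genes_per_cluster: int = 15
    signature_variance_multiplier: float = 3.0
    missing_rate: float = 0.02
    random_pair_loading: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arrays_range[0] < 6:
            raise ValidationError("arrays_range minimum must be >= 6")
        if self.arrays_range[0] > self.arrays_range[1]:
            raise ValidationError("arrays_range must be a nondecreasing interval")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.factor_loading <= 0 or self.noise_sd <= 0:
            raise ValidationError("factor_loading and noise_sd must be positive")
        if self.signature_variance_multiplier <= 1:
            raise ValidationError("signature_variance_multiplier must exceed 1")
        n_pairs = (
            self.n_clusters * self.n_divergent_pairs_per_cluster
            + self.n_coexpressed_pairs
            + self.n_random_pairs
        )
        n_needed = 2 * n_pairs + self.n_clusters * self.signature_genes_per_cluster
        if n_needed > self.n_genes:
            raise ValidationError(
                f"pair and signature demand ({n_needed} genes) exceeds n_genes "
                f"({self.n_genes})"
            )

    @property
    def expected_divergent_r(self) -> float:
        """Within-target-cluster Pearson correlation of a divergent pair."""
        b2 = (self.factor_loading / self.noise_sd) ** 2
        return -b2 / (b2 + 1.0)


@dataclass
class SyntheticTruth:
    pair_class: dict[str, str]  # pair_id -> divergent | coexpressed | random
    target_cluster: dict[str, int]  # divergent pair_id -> cluster id
    dataset_cluster: dict[str, int]  # dataset_id -> cluster id
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        d["target_cluster"] = {k: int(v) for k, v in d["target_cluster"].items()}
        d["dataset_cluster"] = {k: int(v) for k, v in d["dataset_cluster"].items()}
        return cls(**d)


#: pair_class labels used in the generated catalog: divergent pairs play the
#: isozyme role, coexpressed pairs the protein-complex role.
_CLASS_MAP = {"divergent": "isozyme", "coexpressed": "complex", "random": "random"}


def generate_compendium(
    config: SyntheticConfig,
) -> tuple[list[ExpressionDataset], list[GenePair], SyntheticTruth]:
    """Generate a compendium with planted divergence structure.

    Returns the datasets, a pair catalog (divergent pairs labeled
    "isozyme", coexpressed "complex", random "random"), and the ground
    truth. Deterministic given config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]

    # allocate genes: pairs first, then signature genes, rest baseline
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = genes[cursor:cursor + n]
        cursor += n
        return out

    pairs: list[GenePair] = []
    truth_class: dict[str, str] = {}
    truth_target: dict[str, int] = {}
    pid = 0
    divergent: list[tuple[GenePair, int]] = []
    for c in range(1, config.n_clusters + 1):
        for _ in range(config.n_divergent_pairs_per_cluster):
            a, b = take(2)
            pair = GenePair(f"P{pid:03d}", a, b, _CLASS_MAP["divergent"])
            pairs.append(pair)
            truth_class[pair.pair_id] = "divergent"
            truth_target[pair.pair_id] = c
            divergent.append((pair, c))
            pid += 1
    coexpressed: list[GenePair] = []
    for _ in range(config.n_coexpressed_pairs):
        a, b = take(2)
        pair = GenePair(f"P{pid:03d}", a, b, _CLASS_MAP["coexpressed"])
        pairs.append(pair)
        truth_class[pair.pair_id] = "coexpressed"
        coexpressed.append(pair)
        pid += 1
    random_pairs: list[GenePair] = []
    for _ in range(config.n_random_pairs):
        a, b = take(2)
        pair = GenePair(f"P{pid:03d}", a, b, _CLASS_MAP["random"])
        pairs.append(pair)
        truth_class[pair.pair_id] = "random"
        random_pairs.append(pair)
        pid += 1
    signature: dict[int, list[str]] = {
        c: take(config.signature_genes_per_cluster)
        for c in range(1, config.n_clusters + 1)
    }
    gene_index = {g: i for i, g in enumerate(genes)}

    datasets: list[ExpressionDataset] = []
    truth_ds: dict[str, int] = {}
    d_counter = 0
    for c in range(1, config.n_clusters + 1):
        for _ in range(config.datasets_per_cluster):
            ds_id = f"D{d_counter:03d}"
            d_counter += 1
            truth_ds[ds_id] = c
            n_arr = int(rng.integers(config.arrays_range[0],
                                     config.arrays_range[1] + 1))
            values = rng.normal(0.0, config.noise_sd,
                                size=(config.n_genes, n_arr))
            # signature genes: inflated noise SD inside their cluster
            for g in signature[c]:
                values[gene_index[g]] = rng.normal(
                    0.0, config.noise_sd * config.signature_variance_multiplier,
                    size=n_arr,
                )
            # divergent pairs: opposite-sign shared factor in target cluster
            for pair, target in divergent:
                if target != c:
                    continue
                f = rng.normal(0.0, 1.0, size=n_arr)
                values[gene_index[pair.gene_a]] += config.factor_loading * f
                values[gene_index[pair.gene_b]] -= config.factor_loading * f
            # coexpressed pairs: same-sign shared factor everywhere
            for pair in coexpressed:
                f = rng.normal(0.0, 1.0, size=n_arr)
                values[gene_index[pair.gene_a]] += config.factor_loading * f
                values[gene_index[pair.gene_b]] += config.factor_loading * f
            # random pairs: weaker shared factor, signs re-drawn per dataset
            if config.random_pair_loading > 0:
                for pair in random_pairs:
                    f = rng.normal(0.0, 1.0, size=n_arr)
                    s1, s2 = rng.choice([-1.0, 1.0], size=2)
                    values[gene_index[pair.gene_a]] += (
                        s1 * config.random_pair_loading * f
                    )
                    values[gene_index[pair.gene_b]] += (
                        s2 * config.random_pair_loading * f
                    )
            if config.missing_rate > 0:
                mask = rng.random(values.shape) < config.missing_rate
                values = np.where(mask, np.nan, values)
            arrays = [f"{ds_id}_A{j:02d}" for j in range(n_arr)]
            datasets.append(ExpressionDataset(ds_id, list(genes), arrays, values))

    truth = SyntheticTruth(truth_class, truth_target, truth_ds, seed=config.seed)
    return datasets, pairs, truth


def write_compendium(
    datasets: list[ExpressionDataset],
    pairs: list[GenePair],
    truth: SyntheticTruth,
    out_dir,
) -> Path:
    """Persist a generated compendium; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for ds in datasets:
        fname = f"{ds.dataset_id}.pcl"
        cio.write_expression_matrix(ds, out / fname)
        entries.append(
            ManifestEntry(ds.dataset_id, fname, ds.n_arrays,
                          f"cluster {truth.dataset_cluster[ds.dataset_id]}")
        )
    manifest_path = out / "manifest.tsv"
    cio.write_manifest(CompendiumManifest(entries), manifest_path)
    cio.write_pair_catalog(pairs, out / "pairs.tsv")
    truth.to_json(out / "truth.json")
    return manifest_path


# ---------------------------------------------------------------------------
# catalog / pathway fixtures
# ---------------------------------------------------------------------------

#: pathway fixture layout: category -> (n_reactions, n_isozyme_flagged).
#: The glycolysis/gluconeogenesis/fermentation counts (12 reactions, 8
#: isozyme-catalyzed) and the totals (632 reactions, 51 flagged) reflect the
#: yeast pathway catalog; the remaining per-category counts are synthetic
#: and frozen here.
PATHWAY_LAYOUT: dict[str, tuple[int, int]] = {
    "glycolysis_gluconeogenesis_fermentation": (12, 8),
    "pentose_phosphate_pathway": (16, 3),
    "tca_glyoxylate_cycle": (21, 5),
    "storage_carbohydrate": (15, 4),
    "amino_acid_biosynthesis": (150, 10),
    "nucleotide_metabolism": (80, 6),
    "lipid_metabolism": (90, 7),
    "cofactor_metabolism": (100, 5),
    "other": (148, 3),
}


def generate_fixtures() -> tuple[list[IsozymeCandidate], PathwayTable]:
    """Deterministic candidate-catalog and pathway-table fixtures.

    The catalog holds 77 genuine candidate pairs (24 of which fail only the
    same-protein-compartment criterion, leaving 53 retained) plus five
    decoys that fail one of criteria (i)-(iv) (a wrong-reaction pair,
    protein-substrate transferases, a cofactor-differentiated pair, a
    transporter). The pathway table holds 632 reactions, 51 flagged as
    isozyme-catalyzed, with 8 of the 12 glycolysis/gluconeogenesis/
    fermentation reactions flagged.
    """
    candidates: list[IsozymeCandidate] = []
    for i in range(77):
        compartment_ok = i >= 24  # first 24 pairs are compartment-differentiated
        candidates.append(
            IsozymeCandidate(
                pair_id=f"ISO{i:03d}",
                gene_a=f"YA{i:03d}",
                gene_b=f"YB{i:03d}",
                same_reaction=True,
                small_molecule_substrates=True,
                same_cofactor=True,
                reaction_same_compartment=True,
                proteins_same_compartment=compartment_ok,
            )
        )
    decoy_flags = [
        ("DEC000", dict(same_reaction=False)),
        ("DEC001", dict(small_molecule_substrates=False)),  # PMT-like
        ("DEC002", dict(small_molecule_substrates=False)),
        ("DEC003", dict(same_cofactor=False)),
        ("DEC004", dict(reaction_same_compartment=False)),  # transporter
    ]
    for i, (pid, flags) in enumerate(decoy_flags):
        kwargs = dict(
            same_reaction=True,
            small_molecule_substrates=True,
            same_cofactor=True,
            reaction_same_compartment=True,
            proteins_same_compartment=True,
        )
        kwargs.update(flags)
        candidates.append(
            IsozymeCandidate(pair_id=pid, gene_a=f"DA{i:03d}", gene_b=f"DB{i:03d}",
                             **kwargs)
        )

    rows = []
    rid = 0
    for cat, (n, flagged) in PATHWAY_LAYOUT.items():
        for j in range(n):
            rows.append((f"R{rid:04d}", cat, j < flagged))
            rid += 1
    table = PathwayTable(
        pd.DataFrame(rows, columns=["reaction_id", "category", "isozyme_flag"])
    )
    return candidates, table


# ---------------------------------------------------------------------------
# metabolomics fixture
# ---------------------------------------------------------------------------

@dataclass
class MetabolomicsFixture:
    table: MetaboliteTable
    true_slopes: pd.Series
    true_ratios: pd.Series  # mutant/wt linear-scale ratios per metabolite
    isotopes: list[tuple[np.ndarray, IsotopeDistribution]] = field(
        default_factory=list
    )  # (true labeled fractions, forward-simulated observation)


def generate_metabolomics_fixture(
    seed: int = 0,
    n_metabolites: int = 8,
    n_pairs: int = 6,
    drift_slope: float = 0.05,
    mutant_ratio: float = 0.45,
) -> MetabolomicsFixture:
    """Metabolite table with planted run-order drift and strain effects.

    Samples alternate wild type / mutant in run order so each mutant has a
    preceding wild-type partner. Metabolite "M000" carries the planted
    mutant/wild-type ratio; all metabolites carry a linear log2 drift of
    ``drift_slope`` per run-order unit. Also returns noise-free
    mass-isotopomer patterns forward-simulated from known labeled
    fractions for 3-, 6-, and 12-carbon compounds.
    """
    rng = np.random.default_rng(seed)
    mets = [f"M{i:03d}" for i in range(n_metabolites)]
    sample_ids = []
    strains = []
    run_orders = []
    for j in range(n_pairs):
        sample_ids += [f"S{2 * j:02d}", f"S{2 * j + 1:02d}"]
        strains += ["wt", "mut"]
        run_orders += [2 * j + 1, 2 * j + 2]
    volumes = rng.uniform(0.8, 1.2, size=len(sample_ids))
    base = rng.uniform(8.0, 14.0, size=n_metabolites)  # log2 baseline levels
    log2 = np.tile(base[:, None], (1, len(sample_ids)))
    log2 = log2 + drift_slope * np.asarray(run_orders)[None, :]
    is_mut = np.asarray([s == "mut" for s in strains])
    log2[0, is_mut] += np.log2(mutant_ratio)  # planted effect on M000
    intensities = (2.0 ** log2) * volumes[None, :]
    samples = pd.DataFrame(
        {
            "run_order": run_orders,
            "strain": strains,
            "limitation": "glucose",
            "volume": volumes,
        },
        index=sample_ids,
    )
    table = MetaboliteTable(
        values=pd.DataFrame(intensities, index=mets, columns=sample_ids),
        samples=samples,
    )
    ratios = pd.Series(1.0, index=mets)
    ratios["M000"] = mutant_ratio
    isotopes = []
    for n_carbons in (3, 6, 12):
        frac = rng.dirichlet(np.ones(n_carbons + 1))
        isotopes.append((frac, forward_simulate(frac, n_carbons)))
    return MetabolomicsFixture(
        table=table,
        true_slopes=pd.Series(drift_slope, index=mets),
        true_ratios=ratios,
        isotopes=isotopes,
    )
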