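"""Reading and writing the package's tabular artifacts.

Expression matrices are PCL-style TSV: first column holds gene ids, the
remaining columns one array each; values are log-scale. Empty fields,
"NA" and "NaN" (case-insensitive) are missing. Manifests, pair catalogs
and pathway tables are plain TSV; generator truth and pipeline summaries
are JSON. All outputs are UTF-8 with Unix newlines.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CompendiumManifest,
    ExpressionDataset,
    GenePair,
    ManifestEntry,
    PathwayTable,
    ValidationError,
)

MISSING_TOKENS = {"", "na", "nan"}


def _is_missing(tok: str) -> bool:
    return tok.strip().lower() in MISSING_TOKENS


def read_expression_matrix(path: str | os.PathLike, dataset_id: str | None = None) -> ExpressionDataset:
    """Read one PCL-style TSV expression matrix."""
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise IOError(f"cannot read dataset {dataset_id}: {exc}") from exc
    if not lines:
        raise ValidationError(f"dataset {dataset_id}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    array_ids = header[1:]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        fields = ln.split("\t")
        gene = fields[0]
        if gene in gene_ids:
            raise ValidationError(f"dataset {dataset_id}: duplicate gene id {gene!r}")
        vals = [np.nan if _is_missing(f) else float(f) for f in fields[1:]]
        if len(vals) != len(array_ids):
            raise ValidationError(
                f"dataset {dataset_id}: row {gene!r} has {len(vals)} values, "
                f"expected {len(array_ids)}"
            )
        gene_ids.append(gene)
        rows.append(vals)
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(array_ids)))
    return ExpressionDataset(dataset_id, gene_ids, array_ids, values)


def write_expression_matrix(ds: ExpressionDataset, path: str | os.PathLike) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("GENE\t" + "\t".join(ds.array_ids) + "\n")
        for gene, row in zip(ds.gene_ids, ds.values):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


def load_manifest(path: str | os.PathLike) -> CompendiumManifest:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"dataset_id", "path", "n_arrays"}
    if not required.issubset(df.columns):
        raise ValidationError(f"manifest needs columns {sorted(required)}")
    entries = [
        ManifestEntry(
            dataset_id=r.dataset_id,
            path=str((path.parent / r.path)) if not os.path.isabs(r.path) else r.path,
            n_arrays=int(r.n_arrays),
            description=getattr(r, "description", "") or "",
        )
        for r in df.itertuples()
    ]
    return CompendiumManifest(entries)


def write_manifest(manifest: CompendiumManifest, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "dataset_id": e.dataset_id,
                "path": e.path,
                "n_arrays": e.n_arrays,
                "description": e.description,
            }
            for e in manifest.entries
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_compendium(manifest_path: str | os.PathLike) -> list[ExpressionDataset]:
    """Load every dataset referenced by a manifest, in manifest order.

    Datasets with fewer than six arrays are rejected (the compendium rule).
    """
    manifest = load_manifest(manifest_path)
    datasets = []
    for entry in manifest.entries:
        ds = read_expression_matrix(entry.path, dataset_id=entry.dataset_id)
        datasets.append(ds)
    return datasets


def load_pair_catalog(path: str | os.PathLike) -> list[GenePair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pair_id", "gene_a", "gene_b", "pair_class"}
    if not required.issubset(df.columns):
        raise ValidationError(f"pair catalog needs columns {sorted(required)}")
    if df["pair_id"].duplicated().any():
        dup = df.loc[df["pair_id"].duplicated(), "pair_id"].iloc[0]
        raise ValidationError(f"duplicate pair_id {dup!r} in catalog")
    return [
        GenePair(r.pair_id, r.gene_a, r.gene_b, r.pair_class) for r in df.itertuples()
    ]


def write_pair_catalog(pairs: list[GenePair], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "pair_class": p.pair_class,
            }
            for p in pairs
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_pathway_table(path: str | os.PathLike) -> PathwayTable:
    df = pd.read_csv(path, sep="\t")
    df["isozyme_flag"] = df["isozyme_flag"].astype(bool)
    return PathwayTable(df)


def write_pathway_table(table: PathwayTable, path: str | os.PathLike) -> None:
    out = table.frame.copy()
    out["isozyme_flag"] = out["isozyme_flag"].astype(int)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_results(table: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    """Write a results table as TSV with 6-significant-digit floats."""
    try:
        table.to_csv(
            path, sep="\t", index=index, float_format="%.6g", lineterminator="\n"
        )
    except OSError as exc:
        raise IOError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | os.PathLike, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
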