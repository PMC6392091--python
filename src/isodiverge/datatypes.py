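"""Core containers shared across the package.

The unit of analysis is the *dataset*: one experiment's genes x arrays
matrix of log-scale expression values with an explicit missing-value mask.
Correlations between gene pairs are always computed within a dataset, never
across the whole compendium, so that statistics remain comparable between
array platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PAIR_CLASSES = ("isozyme", "complex", "pathway", "random")

MIN_ARRAYS = 6  # datasets with fewer arrays carry too little correlation information


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


@dataclass
class ExpressionDataset:
    """One experiment: genes x arrays log-expression with a missing mask.

    ``values`` is a float matrix (genes x arrays); missing entries are NaN
    and additionally flagged in ``mask`` (True = missing).
    """

    dataset_id: str
    gene_ids: list[str]
    array_ids: list[str]
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.gene_ids), len(self.array_ids)):
            raise ValidationError(
                f"dataset {self.dataset_id}: values shape {self.values.shape} "
                f"does not match {len(self.gene_ids)} genes x {len(self.array_ids)} arrays"
            )
        if self.mask.shape != self.values.shape:
            raise ValidationError(f"dataset {self.dataset_id}: mask shape mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"dataset {self.dataset_id}: duplicate gene ids")
        if len(self.array_ids) < MIN_ARRAYS:
            raise ValidationError(
                f"dataset {self.dataset_id}: {len(self.array_ids)} arrays "
                f"(< {MIN_ARRAYS} required)"
            )
        # keep values/mask consistent
        self.values = np.where(self.mask, np.nan, self.values)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    def gene_row(self, gene: str) -> np.ndarray | None:
        """Return the expression row for ``gene`` (NaN where missing) or None."""
        i = self._gene_index.get(gene)
        return None if i is None else self.values[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.array_ids)


@dataclass
class ManifestEntry:
    dataset_id: str
    path: str
    n_arrays: int
    description: str = ""


@dataclass
class CompendiumManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.dataset_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("manifest contains duplicate dataset ids")


@dataclass(frozen=True)
class GenePair:
    pair_id: str
    gene_a: str
    gene_b: str
    pair_class: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"pair {self.pair_id}: gene_a == gene_b")
        if self.pair_class not in PAIR_CLASSES:
            raise ValidationError(
                f"pair {self.pair_id}: unknown pair_class {self.pair_class!r}"
            )


@dataclass
class PathwayTable:
    """Reactions with a pathway category and an isozyme-catalyzed flag."""

    frame: pd.DataFrame  # columns: reaction_id, category, isozyme_flag

    def __post_init__(self) -> None:
        required = {"reaction_id", "category", "isozyme_flag"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(f"pathway table needs columns {sorted(required)}")
        if self.frame["reaction_id"].duplicated().any():
            raise ValidationError("duplicate reaction ids in pathway table")
        if self.frame["category"].isna().any() or (self.frame["category"] == "").any():
            raise ValidationError("every reaction needs a category")

    @property
    def n_reactions(self) -> int:
        return len(self.frame)

    @property
    def n_isozyme(self) -> int:
        return int(self.frame["isozyme_flag"].sum())


#: Candidate isozyme pair with the five filter annotations.
#: Criteria: (i) same reaction, (ii) small-molecule substrates/products,
#: (iii) same cofactor preference, (iv) reaction in one compartment
#: (excludes transporters), (v) proteins annotated to the same compartment.
@dataclass
class IsozymeCandidate:
    pair_id: str
    gene_a: str
    gene_b: str
    same_reaction: bool
    small_molecule_substrates: bool
    same_cofactor: bool
    reaction_same_compartment: bool
    proteins_same_compartment: bool
    retained: bool | None = None
    failed_criteria: tuple[str, ...] = ()

    CRITERIA = ("i", "ii", "iii", "iv", "v")

    def annotations(self) -> dict[str, bool]:
        return {
            "i": self.same_reaction,
            "ii": self.small_molecule_substrates,
            "iii": self.same_cofactor,
            "iv": self.reaction_same_compartment,
            "v": self.proteins_same_compartment,
        }
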