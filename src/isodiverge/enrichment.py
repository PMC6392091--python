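"""Catalog filtering and pathway enrichment for isozyme-catalyzed reactions.

Candidate isozyme pairs pass five declarative criteria: (i) same reaction,
(ii) small-molecule substrates and products, (iii) same cofactor
preference, (iv) substrates/products in a single compartment (excluding
transporters), (v) both proteins annotated to the same compartment.
Pathway categories are tested for enrichment of isozyme-catalyzed
reactions with the two-tailed Fisher exact test, Holm-adjusted across the
tested categories.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .datatypes import IsozymeCandidate, PathwayTable, ValidationError
from .stats import holm_adjust


def filter_catalog(candidates: list[IsozymeCandidate]) -> list[IsozymeCandidate]:
    """Apply the five filters; returns candidates with retained/failed set.

    A candidate is retained iff every criterion holds; ``failed_criteria``
    records each violated criterion. Idempotent.
    """
    out = []
    for cand in candidates:
        ann = cand.annotations()
        for crit, val in ann.items():
            if val is None or not isinstance(val, (bool, np.bool_)):
                raise ValidationError(
                    f"candidate {cand.pair_id}: missing/invalid annotation "
                    f"for criterion ({crit})"
                )
        failed = tuple(c for c in IsozymeCandidate.CRITERIA if not ann[c])
        out.append(replace(cand, retained=not failed, failed_criteria=failed))
    return out


def retained(candidates: list[IsozymeCandidate]) -> list[IsozymeCandidate]:
    return [c for c in filter_catalog(candidates) if c.retained]


def catalog_frame(candidates: list[IsozymeCandidate]) -> pd.DataFrame:
    """Filtered catalog as a table with a failed_criteria column."""
    filt = filter_catalog(candidates)
    return pd.DataFrame(
        [
            {
                "pair_id": c.pair_id,
                "gene_a": c.gene_a,
                "gene_b": c.gene_b,
                "retained": c.retained,
                "failed_criteria": ",".join(c.failed_criteria),
            }
            for c in filt
        ]
    )


def pathway_enrichment(table: PathwayTable, categories: list[str]) -> pd.DataFrame:
    """Per-category enrichment of isozyme-catalyzed reactions.

    For each listed category, the 2x2 table (in/out of category x
    flagged/unflagged) is tested with the two-tailed Fisher exact test
    (probability-mass method); p-values are Holm-adjusted across the
    listed categories.
    """
    df = table.frame
    rows = []
    for cat in categories:
        in_cat = df["category"] == cat
        if not in_cat.any():
            raise ValidationError(f"category {cat!r} not present in pathway table")
        a = int((in_cat & df["isozyme_flag"]).sum())
        b = int((in_cat & ~df["isozyme_flag"]).sum())
        c = int((~in_cat & df["isozyme_flag"]).sum())
        d = int((~in_cat & ~df["isozyme_flag"]).sum())
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((cat, a, b, c, d, odds, p))
    out = pd.DataFrame(
        rows,
        columns=["category", "in_flagged", "in_unflagged", "out_flagged",
                 "out_unflagged", "odds_ratio", "p_fisher"],
    )
    out["p_holm"] = holm_adjust(out["p_fisher"].to_numpy())
    return out


def overlap_report(
    genes_of_interest: set[str],
    reference_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Fisher-exact overlap of a gene list with reference sets.

    Each reference set is intersected with ``universe``; the 2x2 table of
    (in set) x (in genes_of_interest) over the universe is tested
    two-tailed. A positive log odds ratio indicates enrichment.
    """
    if not universe:
        raise ValidationError("gene universe must be non-empty")
    goi = genes_of_interest & universe
    rows = []
    for name, ref in reference_sets.items():
        ref = ref & universe
        a = len(goi & ref)
        b = len(goi - ref)
        c = len(ref - goi)
        d = len(universe - goi - ref)
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((name, a, b, c, d, odds, p))
    return pd.DataFrame(
        rows, columns=["set", "overlap", "goi_only", "set_only", "neither",
                       "odds_ratio", "p_fisher"]
    )
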