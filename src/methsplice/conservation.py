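"""Cross-species conservation calls and category contrasts.

A gene is conserved in a species when its best protein-alignment hit
there has an E-value strictly below 1e-150.  Genes absent from the
E-value table for a species had no hit and count as non-conserved, so
category proportions are always over the full gene universe.  Contrasts
(methylated vs unmethylated, spliced vs unspliced, and the nested
versions within one category) are 2x2 Fisher exact tests of conserved x
category.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import ContingencyResult, fisher_exact_2x2

__all__ = [
    "CONSERVATION_EVALUE_THRESHOLD",
    "ConservationContrast",
    "load_evalue_table",
    "conserved_genes",
    "conservation_contrast",
]

CONSERVATION_EVALUE_THRESHOLD = 1e-150


@dataclass(frozen=True)
class ConservationContrast:
    """Conservation proportions of two gene categories in one species."""

    species: str
    category_a: str
    category_b: str
    n_a: int
    n_b: int
    proportion_a: float
    proportion_b: float
    p_value: float
    result: ContingencyResult


def load_evalue_table(
    path: str | Path, threshold: float = CONSERVATION_EVALUE_THRESHOLD
) -> pd.DataFrame:
    """Read a best-hit E-value TSV into per-(gene, species) calls.

    Columns: gene_id, species, evalue.  Duplicate (gene, species) rows
    keep the minimum E-value.  The returned frame adds a ``conserved``
    flag, true iff evalue < threshold (strictly; an E-value of exactly
    1e-150 is not conserved).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "species", "evalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["evalue"] = pd.to_numeric(df["evalue"], errors="raise")
    if np.any(df["evalue"] < 0):
        raise ValueError(f"{path}: negative E-value")
    df = (
        df.groupby(["gene_id", "species"], as_index=False, sort=True)["evalue"].min()
    )
    df["conserved"] = df["evalue"] < threshold
    return df


def conserved_genes(calls: pd.DataFrame, species: str) -> set[str]:
    """Gene ids conserved in one species."""
    sub = calls[(calls["species"] == species) & calls["conserved"]]
    return set(sub["gene_id"])


def conservation_contrast(
    calls: pd.DataFrame,
    labels: pd.Series,
    species: str,
    category_a: str = "methylated",
    category_b: str = "unmethylated",
) -> ConservationContrast:
    """Contrast conservation proportions between two gene categories.

    ``labels`` is a boolean Series indexed by gene id over the gene
    universe of the contrast (True = category A).  Restricting the
    universe — e.g. to methylated genes when contrasting spliced vs
    unspliced within them — is done by subsetting ``labels`` before the
    call.  Genes missing from the E-value table are non-conserved.
    An empty category yields an untestable flagged result, not an error.
    """
    cons = conserved_genes(calls, species)
    in_a = labels[labels].index
    in_b = labels[~labels].index
    a = sum(g in cons for g in in_a)
    b = len(in_a) - a
    c = sum(g in cons for g in in_b)
    d = len(in_b) - c
    if len(in_a) == 0 or len(in_b) == 0:
        res = ContingencyResult(
            table=((a, b), (c, d)),
            proportion_a=a / len(in_a) if len(in_a) else float("nan"),
            proportion_b=c / len(in_b) if len(in_b) else float("nan"),
            odds_ratio=float("nan"),
            p_value=float("nan"),
            threshold_context=species,
            testable=False,
        )
    else:
        fisher = fisher_exact_2x2([[a, b], [c, d]])
        res = ContingencyResult(
            table=fisher.table,
            proportion_a=fisher.proportion_a,
            proportion_b=fisher.proportion_b,
            odds_ratio=fisher.odds_ratio,
            p_value=fisher.p_value,
            threshold_context=species,
        )
    return ConservationContrast(
        species=species,
        category_a=category_a,
        category_b=category_b,
        n_a=len(in_a),
        n_b=len(in_b),
        proportion_a=res.proportion_a,
        proportion_b=res.proportion_b,
        p_value=res.p_value,
        result=res,
    )
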