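"""Small shared computations: population doublings, DEG thresholding and
gene-list overlap percentages.

Gene identifiers are normalized (upper-cased, whitespace-stripped) before any
set operation; cross-annotation identifier mapping is out of scope.
"""

from __future__ import annotations

import math
from typing import Iterable

import pandas as pd


def normalize_gene_list(genes: Iterable[str]) -> set[str]:
    """Upper-case and strip identifiers, dropping empties and duplicates."""
    out = set()
    for g in genes:
        g = str(g).strip().upper()
        if g:
            out.add(g)
    return out


def population_doublings(initial_cells: float, final_cells: float) -> float:
    """Population doublings PD = ln(final / initial) / ln 2.

    Negative when the culture lost cells. Both counts must be positive.
    """
    if initial_cells <= 0 or final_cells <= 0:
        raise ValueError("cell counts must be positive")
    return math.log(final_cells / initial_cells) / math.log(2.0)


def deg_filter(
    table: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    abs_lfc_cutoff: float = 2.0,
    gene_col: str = "gene",
    lfc_col: str = "log2FC",
    fdr_col: str = "FDR",
) -> set[str]:
    """Differentially expressed genes at FDR < cutoff and |log2FC| > cutoff.

    Both inequalities are strict: a gene at exactly FDR 0.05 or |log2FC| 2
    is dropped.
    """
    for col in (gene_col, lfc_col, fdr_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    fdr = table[fdr_col].astype(float)
    if ((fdr < 0) | (fdr > 1)).any():
        raise ValueError("FDR values must lie in [0, 1]")
    keep = (fdr < fdr_cutoff) & (table[lfc_col].astype(float).abs() > abs_lfc_cutoff)
    return normalize_gene_list(table.loc[keep, gene_col])


def list_overlap_percent(
    a: Iterable[str], b: Iterable[str], denominator: str = "a"
) -> float:
    """100 * |a ∩ b| / |denominator list|, denominator in {'a', 'b', 'union'}.

    Overlap percentages between gene lists are asymmetric, so the denominator
    choice is explicit and part of the result's meaning.
    """
    set_a = normalize_gene_list(a)
    set_b = normalize_gene_list(b)
    if denominator == "a":
        denom = set_a
    elif denominator == "b":
        denom = set_b
    elif denominator == "union":
        denom = set_a | set_b
    else:
        raise ValueError("denominator must be 'a', 'b' or 'union'")
    if not denom:
        raise ValueError("empty denominator list")
    return 100.0 * len(set_a & set_b) / len(denom)
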