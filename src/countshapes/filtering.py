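"""Prevalence filtering and cross-condition gene intersection.

Genes with nonzero expression in at least ``min_fraction`` (default 10%) of
the cells within a condition are retained for that condition; downstream
modeling is restricted to the genes common to every condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CellDesign, CountMatrix


@dataclass
class FilterReport:
    """Per-condition retained genes plus the nonzero fractions behind them."""

    retained: dict[str, list[str]]
    fractions: pd.DataFrame  # genes x conditions, nonzero fraction
    gene_order: list[str]

    def common_genes(self) -> list[str]:
        return intersect_conditions(self)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond in self.fractions.columns:
            kept = set(self.retained[cond])
            for gene in self.gene_order:
                rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "nonzero_fraction": self.fractions.at[gene, cond],
                        "retained": gene in kept,
                    }
                )
        return pd.DataFrame(rows)


def filter_genes_by_condition(
    matrix: CountMatrix, design: CellDesign, min_fraction: float = 0.10
) -> FilterReport:
    """Retain a gene for a condition iff its nonzero fraction there is >= min_fraction."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    col_of = {c: j for j, c in enumerate(matrix.cells)}
    fractions = {}
    retained = {}
    for cond in design.conditions:
        cells = design.cells_in(cond)
        idx = [col_of[c] for c in cells if c in col_of]
        if not idx:
            raise ValueError(f"condition {cond!r} has no cells in the count matrix")
        frac = (matrix.counts[:, idx] > 0).mean(axis=1)
        fractions[cond] = frac
        keep = frac >= min_fraction
        retained[cond] = [g for g, k in zip(matrix.genes, keep) if k]
    frame = pd.DataFrame(fractions, index=list(matrix.genes))
    return FilterReport(retained=retained, fractions=frame, gene_order=list(matrix.genes))


def intersect_conditions(report: FilterReport) -> list[str]:
    """Genes retained in every condition, in the input matrix's gene order."""
    if not report.retained:
        raise ValueError("report has no conditions")
    common = set(report.gene_order)
    for genes in report.retained.values():
        common &= set(genes)
    return [g for g in report.gene_order if g in common]
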