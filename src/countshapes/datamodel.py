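"""Core data containers: the UMI count matrix and the per-cell design."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Input data violates a format contract (non-integer counts etc.)."""


class InputError(ValueError):
    """A required input file or column is missing."""


@dataclass
class CountMatrix:
    """Gene x cell matrix of non-negative integer UMI counts.

    Rows are genes, columns are cell barcodes; ``counts[i, j]`` is the
    deduplicated transcript count y_ij of gene i in cell j.
    """

    genes: list[str]
    cells: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts)
            if not np.allclose(self.counts, as_int, rtol=0, atol=1e-9):
                raise FormatError("counts contain non-integer values")
            self.counts = as_int.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("counts contain negative values")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("gene identifiers are not unique")
        if len(set(self.cells)) != len(self.cells):
            raise FormatError("cell barcodes are not unique")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def row(self, gene: str) -> np.ndarray:
        return self.counts[self.genes.index(gene)]

    def subset_genes(self, keep: list[str]) -> "CountMatrix":
        idx = [self.genes.index(g) for g in keep]
        return CountMatrix(list(keep), list(self.cells), self.counts[idx])

    def subset_cells(self, keep: list[str]) -> "CountMatrix":
        idx = [self.cells.index(c) for c in keep]
        return CountMatrix(list(self.genes), list(keep), self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.cells)


@dataclass
class CellDesign:
    """Per-cell metadata: condition label, covariates and library size N_c.

    ``table`` is indexed by cell barcode and must contain the condition
    column; ``library_size`` (total UMI count of the cell, the GLM offset
    base) is stored as a column named ``library_size``.
    """

    table: pd.DataFrame
    condition: str = "condition"
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.condition not in self.table.columns:
            raise InputError(f"condition column {self.condition!r} missing from design")
        for cov in self.covariates:
            if cov not in self.table.columns:
                raise InputError(f"covariate column {cov!r} missing from design")
        if "library_size" in self.table.columns:
            sizes = self.table["library_size"]
            if (sizes <= 0).any():
                raise FormatError("library_size must be > 0 for every modeled cell")

    @property
    def cells(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table[self.condition].unique())

    def cells_in(self, condition: str) -> list[str]:
        if condition not in set(self.table[self.condition]):
            raise InputError(f"condition {condition!r} absent from design")
        return list(self.table.index[self.table[self.condition] == condition])

    def library_sizes(self) -> pd.Series:
        if "library_size" not in self.table.columns:
            raise InputError("design has no library_size column; call attach_library_sizes")
        return self.table["library_size"]

    def attach_library_sizes(self, sizes: pd.Series) -> "CellDesign":
        table = self.table.copy()
        table["library_size"] = sizes.reindex(table.index)
        return CellDesign(table, self.condition, list(self.covariates))

    def subset(self, cells: list[str]) -> "CellDesign":
        return CellDesign(self.table.loc[cells], self.condition, list(self.covariates))

    def validate_against(self, matrix: CountMatrix) -> None:
        missing = set(matrix.cells) - set(self.table.index)
        if missing:
            raise InputError(
                f"{len(missing)} cells in the count matrix have no design row "
                f"(e.g. {sorted(missing)[:3]})"
            )
        counts = self.table.loc[list(matrix.cells), self.condition].value_counts()
        small = counts[counts < 2]
        if len(small):
            raise InputError(
                f"conditions with fewer than 2 cells: {list(small.index)}"
            )
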