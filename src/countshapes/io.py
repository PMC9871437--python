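"""Readers and writers: 10X MatrixMarket triplets, delimited matrices, TSV results.

The 10X convention stores the matrix features x barcodes; orientation on disk
is nevertheless inferred by matching matrix dimensions against the lengths of
the barcode and feature files, so transposed exports are read correctly.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datamodel import CellDesign, CountMatrix, FormatError, InputError

log = logging.getLogger(__name__)

_MTX_NAMES = ("matrix.mtx", "matrix.mtx.gz")
_BARCODE_NAMES = ("barcodes.tsv", "barcodes.tsv.gz")
_FEATURE_NAMES = ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz")


def _find(directory: Path, names: tuple[str, ...], what: str) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise InputError(f"no {what} file in {directory} (looked for {', '.join(names)})")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _dedupe(names: list[str]) -> list[str]:
    """Disambiguate duplicates deterministically with a numeric suffix."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_counts_10x(directory_path) -> CountMatrix:
    """Read a 10X-style directory (matrix.mtx + barcodes.tsv + features/genes.tsv).

    Returns genes x cells regardless of on-disk orientation; the ambiguous
    square case is resolved as features x barcodes (the 10X convention).
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    mtx_path = _find(directory, _MTX_NAMES, "MatrixMarket matrix")
    barcode_path = _find(directory, _BARCODE_NAMES, "barcode")
    feature_path = _find(directory, _FEATURE_NAMES, "feature/gene")

    mat = spio.mmread(str(mtx_path))
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if not np.allclose(mat, np.rint(mat), rtol=0, atol=1e-9):
        raise FormatError(f"{mtx_path} contains non-integer values")
    mat = np.rint(mat).astype(np.int64)

    barcodes = [line.split("\t")[0] for line in _read_lines(barcode_path)]
    features = [line.split("\t")[0] for line in _read_lines(feature_path)]

    n_feat, n_bc = len(features), len(barcodes)
    if mat.shape == (n_feat, n_bc):
        pass  # features x barcodes (also covers the ambiguous square case)
    elif mat.shape == (n_bc, n_feat):
        mat = mat.T
    else:
        raise InputError(
            f"matrix shape {mat.shape} matches neither {n_feat} features x "
            f"{n_bc} barcodes nor its transpose"
        )
    return CountMatrix(_dedupe(features), _dedupe(barcodes), mat)


def read_counts_table(path, delimiter: str = "\t") -> CountMatrix:
    """Read a delimited matrix: first column gene IDs, header row barcodes."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path} contains non-numeric cells")
    if np.isnan(values.astype(float)).any():
        raise FormatError(f"{path} contains missing values")
    as_int = np.rint(values.astype(float))
    if not np.allclose(values.astype(float), as_int, rtol=0, atol=1e-9):
        raise FormatError(f"{path} contains non-integer counts")
    if (as_int < 0).any():
        raise FormatError(f"{path} contains negative counts")
    return CountMatrix(
        [str(g) for g in df.index], [str(c) for c in df.columns], as_int.astype(np.int64)
    )


def compute_library_sizes(matrix: CountMatrix) -> pd.Series:
    """Total UMI count per cell (column sums). Zero-sum cells are flagged."""
    sizes = pd.Series(
        matrix.counts.sum(axis=0), index=list(matrix.cells), name="library_size"
    )
    empty = sizes.index[sizes == 0]
    if len(empty):
        log.warning(
            "%d cells have library size 0 and should be excluded before modeling: %s",
            len(empty),
            list(empty[:5]),
        )
    return sizes


def drop_empty_cells(matrix: CountMatrix, design: CellDesign | None = None):
    """Drop cells whose library size is 0 (they carry no information)."""
    sizes = compute_library_sizes(matrix)
    keep = [c for c in matrix.cells if sizes[c] > 0]
    if len(keep) < matrix.n_cells:
        log.warning("dropping %d zero-count cells", matrix.n_cells - len(keep))
        matrix = matrix.subset_cells(keep)
        if design is not None:
            design = design.subset(keep)
    return (matrix, design) if design is not None else matrix


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as TSV: stable column order, 'NA' for missing,
    >= 6 significant digits on floats, round-trippable via read_results."""
    if table.empty:
        raise ValueError("refusing to write an empty results table")
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.8g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)


def read_cell_metadata(path, condition: str, covariates: list[str] | None = None) -> CellDesign:
    """Read a cell-metadata TSV (first column barcode) into a CellDesign."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    return CellDesign(table, condition=condition, covariates=list(covariates or []))
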