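"""Readers and writers for expression matrices and tables.

On-disk formats: MatrixMarket MTX (values) with two sidecar newline-delimited
id files (``<stem>.rows.txt`` for cell/voxel ids, ``<stem>.cols.txt`` for
gene ids), or dense CSV/TSV with a header row of gene ids and the first
column holding cell/voxel ids.  Integer matrices round-trip bit-exactly.
MTX on disk is 1-based per the format standard; everything in memory is
0-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .data_model import AnnotationTable, SingleCellMatrix, SpatialMatrix

__all__ = ["read_matrix", "write_matrix", "read_labels", "read_annotations",
           "read_vector_csv", "write_vector_csv"]


def _id_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".rows.txt"), stem.with_suffix(".cols.txt")


def _read_ids(path: Path) -> np.ndarray:
    return np.asarray(path.read_text().splitlines(), dtype=object)


def read_matrix(path, kind: str = "sc", fmt: str | None = None):
    """Read an expression matrix as a :class:`SingleCellMatrix` (``kind="sc"``)
    or :class:`SpatialMatrix` (``kind="spatial"``)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        rows_p, cols_p = _id_paths(path)
        values = spio.mmread(path)
        if sparse.issparse(values):
            values = values.toarray()
        values = np.asarray(values, dtype=float)
        row_ids, col_ids = _read_ids(rows_p), _read_ids(cols_p)
        if values.shape != (len(row_ids), len(col_ids)):
            raise ValueError(
                f"{path}: MTX dims {values.shape} do not match id files "
                f"({len(row_ids)}, {len(col_ids)})")
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        with open(path) as fh:  # pandas mangles duplicate headers silently
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValueError(f"{path}: duplicate gene columns")
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.duplicated().any():
            raise ValueError(f"{path}: duplicate row ids")
        values = df.to_numpy(dtype=float)
        row_ids = np.asarray(df.index.astype(str), dtype=object)
        col_ids = np.asarray(df.columns.astype(str), dtype=object)
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    if kind == "sc":
        return SingleCellMatrix(values, row_ids, col_ids)
    if kind == "spatial":
        return SpatialMatrix(values, row_ids, col_ids)
    raise ValueError(f"unknown kind {kind!r}")


def write_matrix(m, path, fmt: str | None = None) -> None:
    """Write a matrix; inverse of :func:`read_matrix` (lossless for integers)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    row_ids = m.cell_ids if isinstance(m, SingleCellMatrix) else m.voxel_ids
    values = m.values
    if fmt == "mtx":
        integral = np.all(values == np.round(values))
        mat = sparse.coo_matrix(values.astype(np.int64) if integral else values)
        spio.mmwrite(path, mat, field="integer" if integral else "real")
        rows_p, cols_p = _id_paths(path)
        rows_p.write_text("\n".join(map(str, row_ids)) + "\n")
        cols_p.write_text("\n".join(map(str, m.gene_ids)) + "\n")
    elif fmt in ("csv", "tsv"):
        integral = np.all(values == np.round(values))
        df = pd.DataFrame(values.astype(np.int64) if integral else values,
                          index=row_ids, columns=m.gene_ids)
        df.to_csv(path, sep="," if fmt == "csv" else "\t")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_labels(path, id_column: str = None, label_column: str = None) -> pd.Series:
    """Per-cell label CSV: first column = cell id, second = label (or named)."""
    df = pd.read_csv(path)
    idc = id_column or df.columns[0]
    labc = label_column or df.columns[1]
    return pd.Series(df[labc].astype(str).to_numpy(),
                     index=df[idc].astype(str), name="label")


def read_annotations(path) -> AnnotationTable:
    """Numeric annotation CSV: first column = cell id, remaining numeric."""
    df = pd.read_csv(path, index_col=0)
    return AnnotationTable(df.to_numpy(dtype=float),
                           np.asarray(df.index.astype(str), dtype=object),
                           np.asarray(df.columns.astype(str), dtype=object),
                           encoding="numeric")


def read_vector_csv(path, column: str | None = None) -> np.ndarray:
    """Per-voxel vector CSV (e.g. segmented-cell counts): id column + value."""
    df = pd.read_csv(path)
    col = column or df.columns[-1]
    return df[col].to_numpy(dtype=float)


def write_vector_csv(ids, values, path, column: str = "value") -> None:
    pd.DataFrame({"id": ids, column: values}).to_csv(path, index=False)
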