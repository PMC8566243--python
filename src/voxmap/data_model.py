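"""Containers and validators for the cell-to-voxel mapping problem.

The mapping problem works on two expression matrices — ``S`` (cells x genes,
single-cell or single-nucleus profiles) and ``G`` (voxels x genes, spatial
measurements) — plus an optional per-voxel cell-density prior ``d`` that lives
on the probability simplex.  The two matrices need not share units of measure;
they only need to share a subset of gene identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SingleCellMatrix",
    "SpatialMatrix",
    "DensityPrior",
    "AnnotationTable",
    "ValidationReport",
    "validate",
    "intersect_genes",
    "normalize_library_size",
    "log1p_transform",
    "compute_sparsity",
    "density_from_segmentation",
    "uniform_density",
]

_SIMPLEX_TOL = 1e-9


def _check_ids(ids, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what}")
    return ids


def _check_values(values, n_rows_ids, n_cols_ids, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"{what}: values must be 2-D")
    if values.shape != (n_rows_ids, n_cols_ids):
        raise ValueError(
            f"{what}: shape {values.shape} does not match id counts "
            f"({n_rows_ids}, {n_cols_ids})"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: non-finite entries")
    if np.any(values < 0):
        raise ValueError(f"{what}: negative entries")
    return values


@dataclass(frozen=True)
class SingleCellMatrix:
    """Cells x genes non-negative expression matrix ``S``.

    Parameters
    ----------
    values
        Non-negative, finite expression values (arbitrary units).
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    labels
        Optional per-cell categorical annotation (e.g. cell type).
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self):
        cell_ids = _check_ids(self.cell_ids, "cell_ids")
        gene_ids = _check_ids(self.gene_ids, "gene_ids")
        values = _check_values(self.values, len(cell_ids), len(gene_ids), "SingleCellMatrix")
        labels = self.labels
        if labels is not None:
            labels = np.asarray(labels, dtype=object)
            if labels.shape != (len(cell_ids),):
                raise ValueError("labels length must equal n_cells")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", cell_ids)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "labels", labels)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class SpatialMatrix:
    """Voxels x genes non-negative expression matrix ``G``.

    A "voxel" is one spatial measurement unit: a segmented cell for targeted
    in situ data, or a barcoded spot for array-based spatial transcriptomics.
    ``coords`` (voxels x 2) is carried for plotting/export only.
    """

    values: np.ndarray
    voxel_ids: np.ndarray
    gene_ids: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self):
        voxel_ids = _check_ids(self.voxel_ids, "voxel_ids")
        gene_ids = _check_ids(self.gene_ids, "gene_ids")
        values = _check_values(self.values, len(voxel_ids), len(gene_ids), "SpatialMatrix")
        coords = self.coords
        if coords is not None:
            coords = np.asarray(coords, dtype=float)
            if coords.shape != (len(voxel_ids), 2):
                raise ValueError("coords must be voxels x 2")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_ids", voxel_ids)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "coords", coords)

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.voxel_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class DensityPrior:
    """Expected per-voxel cell density ``d`` — a probability simplex vector."""

    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("density must be a nonempty 1-D vector")
        if not np.all(np.isfinite(d)):
            raise ValueError("density has non-finite entries")
        if np.any(d < 0) or np.any(d > 1):
            raise ValueError("density entries must lie in [0, 1]")
        if abs(d.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"density must sum to 1 (got {d.sum()!r})")
        object.__setattr__(self, "d", d)

    @property
    def n_voxels(self) -> int:
        return self.d.size


@dataclass(frozen=True)
class AnnotationTable:
    """Cells x annotations numeric matrix ``A``.

    Categorical annotations (cell types) are one-hot encoded, with
    ``encoding="one-hot-categorical"``; numeric annotations (e.g. chromatin
    accessibility peak counts or motif scores) use ``encoding="numeric"``.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    annotation_ids: np.ndarray
    encoding: str = "numeric"

    def __post_init__(self):
        cell_ids = _check_ids(self.cell_ids, "cell_ids")
        annotation_ids = _check_ids(self.annotation_ids, "annotation_ids")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(cell_ids), len(annotation_ids)):
            raise ValueError("AnnotationTable shape does not match id counts")
        if not np.all(np.isfinite(values)):
            raise ValueError("AnnotationTable has non-finite entries")
        if self.encoding not in ("numeric", "one-hot-categorical"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.encoding == "one-hot-categorical":
            row_sums = values.sum(axis=1)
            if not np.allclose(row_sums, 1.0, atol=_SIMPLEX_TOL):
                raise ValueError("one-hot rows must sum to 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", cell_ids)
        object.__setattr__(self, "annotation_ids", annotation_ids)

    @classmethod
    def from_labels(cls, cell_ids, labels) -> "AnnotationTable":
        """One-hot encode a categorical label vector (column order = sorted labels)."""
        labels = np.asarray(labels, dtype=object)
        categories = sorted(set(labels))
        values = np.zeros((len(labels), len(categories)))
        index = {c: t for t, c in enumerate(categories)}
        for i, lab in enumerate(labels):
            values[i, index[lab]] = 1.0
        return cls(values, cell_ids, np.asarray(categories, dtype=object),
                   encoding="one-hot-categorical")


@dataclass
class ValidationReport:
    """Outcome of cross-checking the inputs of one mapping problem."""

    violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


def validate(sc: SingleCellMatrix, sp: SpatialMatrix,
             density: DensityPrior | None = None) -> ValidationReport:
    """Cross-validate a mapping problem's inputs.

    Container invariants (non-negativity, finiteness, unique ids, simplex
    density) are enforced at construction; this checks the *joint* conditions:
    nonempty matrices, at least one shared gene, and density length matching
    the number of voxels.  Empty matrices and disjoint gene panels are hard
    errors because no mapping is definable.
    """
    if sc.n_cells == 0 or sc.n_genes == 0 or sp.n_voxels == 0 or sp.n_genes == 0:
        raise ValueError("empty expression matrix")
    shared = set(sc.gene_ids) & set(sp.gene_ids)
    if not shared:
        raise ValueError("the two modalities share no common genes")
    report = ValidationReport()
    if density is not None and density.n_voxels != sp.n_voxels:
        report.violations.append(
            f"density length {density.n_voxels} != n_voxels {sp.n_voxels}"
        )
    return report


def intersect_genes(sc: SingleCellMatrix, sp: SpatialMatrix,
                    panel: list[str] | None = None
                    ) -> tuple[SingleCellMatrix, SpatialMatrix]:
    """Restrict both modalities to a common ordered gene list.

    The shared list is the intersection of the two gene panels, further
    intersected with ``panel`` when given.  Order follows ``panel`` when
    provided, else lexicographic.  Gene-id matching is exact, case-sensitive.
    """
    shared = set(sc.gene_ids) & set(sp.gene_ids)
    if panel is not None:
        ordered = [g for g in panel if g in shared]
    else:
        ordered = sorted(shared)
    if not ordered:
        raise ValueError("no shared genes after intersection")
    sc_idx = {g: i for i, g in enumerate(sc.gene_ids)}
    sp_idx = {g: i for i, g in enumerate(sp.gene_ids)}
    sc_cols = [sc_idx[g] for g in ordered]
    sp_cols = [sp_idx[g] for g in ordered]
    gene_ids = np.asarray(ordered, dtype=object)
    sc_out = replace(sc, values=sc.values[:, sc_cols], gene_ids=gene_ids)
    sp_out = replace(sp, values=sp.values[:, sp_cols], gene_ids=gene_ids)
    return sc_out, sp_out


def normalize_library_size(m, target_sum: float = 1e4):
    """Rescale each row (cell or voxel) to a common total count.

    Corrects for library-size differences between profiles.  Rows with zero
    total are rejected — a profile with no counts carries no information and
    cannot be rescaled.
    """
    totals = m.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = m.cell_ids if isinstance(m, SingleCellMatrix) else m.voxel_ids
        raise ValueError(f"all-zero row(s): {list(ids[zero[:5]])}")
    scaled = m.values * (target_sum / totals)[:, None]
    return replace(m, values=scaled)


def log1p_transform(m):
    """Elementwise natural log(1 + x); standard variance-stabilizing step."""
    if np.any(m.values < 0):
        raise ValueError("negative entries")
    return replace(m, values=np.log1p(m.values))


def compute_sparsity(sp: SpatialMatrix) -> np.ndarray:
    """Per-gene fraction of voxels where the gene is undetected (value == 0).

    Evaluated on the matrix as given; callers wanting raw-count sparsity
    should call this before any normalization.
    """
    return (sp.values == 0).mean(axis=0)


def density_from_segmentation(counts) -> DensityPrior:
    """Density prior from per-voxel segmented-cell counts: d_j = c_j / sum(c)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("counts must be 1-D")
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero segmentation counts")
    d = counts / total
    # guard the simplex invariant against accumulated rounding
    d = d / d.sum()
    return DensityPrior(d)


def uniform_density(n_voxels: int) -> DensityPrior:
    """Uniform prior d_j = 1/n_voxels, used for single-cell-resolution data."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    return DensityPrior(np.full(n_voxels, 1.0 / n_voxels))
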