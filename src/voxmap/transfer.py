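"""Projecting annotations, genes and cell types into space from a mapping.

Any per-cell quantity — one-hot cell types, genome-wide expression, chromatin
accessibility scores — is transferred onto voxels by the matrix product
``A_transf = M^T A`` (or ``M^T diag(f) A`` when a filter was learned).  For
single-cell-resolution voxels a deterministic cell-type call takes the most
probable cell per voxel; for multi-cell spots, deconvolution places filtered
cells into their most probable voxel and matches them to segmented cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AnnotationTable, SingleCellMatrix
from .mapper import MappingResult

__all__ = ["SpatialProjection", "DeconvolutionAssignment", "project_annotations",
           "project_genes", "deterministic_celltype_map", "deconvolve",
           "FILTER_THRESHOLD"]

FILTER_THRESHOLD = 0.5  # a cell counts as "mapped" when f_i exceeds this


@dataclass(frozen=True)
class SpatialProjection:
    """Voxels x annotations (or voxels x genes) projected matrix."""

    values: np.ndarray
    voxel_ids: np.ndarray
    annotation_ids: np.ndarray
    used_filter: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.voxel_ids,
                            columns=self.annotation_ids)


@dataclass(frozen=True)
class DeconvolutionAssignment:
    """Per segmented cell: voxel, assigned single-cell profile and its label.

    ``table`` columns: voxel_id, segmented_cell_index, sc_cell_id, label —
    with sc_cell_id/label empty strings for segmented cells that received no
    mapped profile.  ``unplaced_cells`` lists profile ids that passed the
    filter but exceeded their voxel's segmented count.
    """

    table: pd.DataFrame
    unplaced_cells: list[str]


def _check_cells(result: MappingResult, cell_ids) -> None:
    if not np.array_equal(np.asarray(cell_ids, dtype=object), result.cell_ids):
        raise ValueError("cell ids are not aligned with the mapping's cells")


def project_annotations(result: MappingResult, annotations: AnnotationTable,
                        use_filter: bool = False) -> SpatialProjection:
    """Transfer annotations into space: ``M^T A``, or ``M^T (diag(f) A)``.

    With one-hot cell-type annotations and no filter, the result is the
    probabilistic count of each type in each voxel, and column totals equal
    the per-type cell counts exactly (rows of M sum to 1).
    """
    _check_cells(result, annotations.cell_ids)
    A = annotations.values
    if use_filter:
        if result.f is None:
            raise ValueError("mapping has no learned filter")
        A = result.f[:, None] * A
    return SpatialProjection(result.M.T @ A, result.voxel_ids,
                             annotations.annotation_ids, used_filter=use_filter)


def project_genes(result: MappingResult, sc_full: SingleCellMatrix,
                  use_filter: bool = False) -> SpatialProjection:
    """Predicted spatial expression ``M^T S`` over *all* genes of ``sc_full``.

    ``sc_full`` may contain genes never used in training; this is the
    imputation surface for held-out and genome-wide genes.
    """
    _check_cells(result, sc_full.cell_ids)
    S = sc_full.values
    if use_filter:
        if result.f is None:
            raise ValueError("mapping has no learned filter")
        S = result.f[:, None] * S
    return SpatialProjection(result.M.T @ S, result.voxel_ids,
                             sc_full.gene_ids, used_filter=use_filter)


def deterministic_celltype_map(result: MappingResult, labels) -> pd.Series:
    """Most-likely cell type per voxel, for single-cell-resolution data.

    Per voxel j the call is the label of ``argmax_i M_ij`` among retained
    cells (filter > 0.5 when a filter exists); ties break to the lowest cell
    index.  A voxel with no retained cell is flagged ``"<unassigned>"``.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != result.n_cells:
        raise ValueError("labels length must equal n_cells")
    M = result.M.copy()
    if result.f is not None:
        M[result.f <= FILTER_THRESHOLD] = -np.inf
    calls = []
    for j in range(result.n_voxels):
        col = M[:, j]
        if not np.any(np.isfinite(col)):
            calls.append("<unassigned>")
        else:
            calls.append(labels[int(np.argmax(col))])
    return pd.Series(calls, index=result.voxel_ids, name="cell_type")


def deconvolve(result: MappingResult, labels, seg_counts,
               seed: int = 0) -> DeconvolutionAssignment:
    """Resolve multi-cell spots into individually typed segmented cells.

    Cells passing the filter (f > 0.5) are placed in their argmax voxel; in
    each voxel the placed profiles are matched to that voxel's segmented
    cells uniformly at random (seeded, independent of the mapping seed).
    Surplus segmented cells are left unassigned; surplus profiles (more
    placed than segmented in a voxel) are reported unplaced.
    """
    if result.f is None:
        raise ValueError("deconvolution requires a filtered-mode mapping")
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != result.n_cells:
        raise ValueError("labels length must equal n_cells")
    seg_counts = np.asarray(seg_counts, dtype=int)
    if seg_counts.shape[0] != result.n_voxels:
        raise ValueError("seg_counts length must equal n_voxels")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5e9]))
    passed = np.flatnonzero(result.f > FILTER_THRESHOLD)
    best_voxel = result.M[passed].argmax(axis=1)

    rows = []
    unplaced: list[str] = []
    for j in range(result.n_voxels):
        cells_here = passed[best_voxel == j]
        n_seg = int(seg_counts[j])
        if len(cells_here) > n_seg:
            # more mapped profiles than segmented cells: keep the most
            # probable ones, report the rest unplaced
            order = np.argsort(-result.M[cells_here, j], kind="stable")
            keep, drop = cells_here[order[:n_seg]], cells_here[order[n_seg:]]
            unplaced.extend(result.cell_ids[drop])
            cells_here = keep
        slots = rng.permutation(n_seg)[:len(cells_here)]
        assigned = {int(s): c for s, c in zip(slots, cells_here)}
        for s in range(n_seg):
            if s in assigned:
                c = assigned[s]
                rows.append((result.voxel_ids[j], s, result.cell_ids[c], labels[c]))
            else:
                rows.append((result.voxel_ids[j], s, "", ""))
    table = pd.DataFrame(rows, columns=["voxel_id", "segmented_cell_index",
                                        "sc_cell_id", "label"])
    return DeconvolutionAssignment(table=table, unplaced_cells=unplaced)
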