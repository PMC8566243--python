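"""Ground-truth fixture generator for the mapping problem.

Emulates the data regime the mapping method targets: a handful of cell types
with distinct expression signatures, a spatially structured tissue (layered
bands of types, mimicking cortical layers), single-cell profiles measured
with Poisson count noise, and a spatial modality obtained by aggregating the
cells placed in each voxel, degraded by Poisson noise, Bernoulli dropout
(technical zeros) and an arbitrary unit-of-measure scale factor.

Because cell placement is known exactly, every downstream claim — cell-type
recovery, holdout-gene imputation, filter selection — can be scored against
ground truth.  All draws come from named substreams of one seed, so a
:class:`SyntheticTruth` regenerates bit-identically from its parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data_model import SingleCellMatrix, SpatialMatrix

__all__ = ["SyntheticParams", "SyntheticTruth", "generate_profiles",
           "generate_tissue", "render_spatial", "make_truth", "standard_suite",
           "voxel_true_labels"]


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; the standard suite uses the defaults below."""

    n_types: int = 5
    n_genes: int = 200
    markers_per_type: int = 20
    effect: float = 8.0          # fold-elevation of a type's marker block
    n_voxels: int = 100
    layout: str = "layered"
    mean_cells_per_voxel: float = 3.0
    purity: float = 0.8          # occupancy weight of a band's dominant type
    sc_depth: float = 10.0       # Poisson depth of the single-cell measurement
    poisson_rate: float = 1.0    # spatial sequencing-depth multiplier (0 = noiseless)
    dropout_prob: float = 0.0
    unit_scale: float = 1.0
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Fixture with known ground truth.

    ``placement[i]`` is the voxel index of cell i; ``seg_counts`` the number
    of placed cells per voxel; ``type_occupancy`` the voxels x types mixture
    the placements were drawn from; ``signatures`` the types x genes clean
    profiles.
    """

    sc: SingleCellMatrix
    sp: SpatialMatrix
    placement: np.ndarray
    type_occupancy: np.ndarray
    seg_counts: np.ndarray
    signatures: np.ndarray
    type_names: list[str]
    params: SyntheticParams = field(default_factory=SyntheticParams)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ["profiles", "tissue", "sc", "spatial"]
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def generate_profiles(n_types: int, n_genes: int, markers_per_type: int,
                      effect: float, seed: int = 0) -> np.ndarray:
    """Types x genes signature matrix with disjoint elevated marker blocks.

    Baseline expression per gene is drawn once (uniform in [0.5, 1.5]) and
    shared across types; type t's marker block (genes
    ``[t*markers_per_type, (t+1)*markers_per_type)``) is multiplied by
    ``effect``.  ``effect=1`` is the degenerate control with identical types.
    """
    if n_types * markers_per_type > n_genes:
        raise ValueError("marker blocks exceed the number of genes")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    baseline = rng.uniform(0.5, 1.5, size=n_genes)
    signatures = np.tile(baseline, (n_types, 1))
    for t in range(n_types):
        lo = t * markers_per_type
        signatures[t, lo:lo + markers_per_type] *= effect
    return signatures


def generate_tissue(n_voxels: int, n_types: int, layout: str = "layered",
                    seed: int = 0, mean_cells_per_voxel: float = 3.0,
                    purity: float = 0.8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Type occupancy, cell placement, and cell types for a synthetic tissue.

    ``layered`` splits the voxel axis into ``n_types`` contiguous bands, each
    dominated (weight ``purity``) by one type with the remainder spread over
    the others; ``random`` uses uniform occupancy.  Per voxel, the number of
    resident cells is 1 + Poisson(mean - 1) and each cell's type is drawn
    from the voxel's occupancy row.

    Returns ``(occupancy [voxels x types], placement [n_cells], cell_types
    [n_cells])`` with placement sorted by voxel.
    """
    if layout not in ("layered", "random"):
        raise ValueError(f"unknown layout {layout!r}")
    if layout == "layered" and n_voxels < n_types:
        raise ValueError("layered layout needs n_voxels >= n_types")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if layout == "layered":
        band = np.minimum(np.arange(n_voxels) * n_types // n_voxels, n_types - 1)
        if n_types == 1:
            occupancy = np.ones((n_voxels, 1))
        else:
            occupancy = np.full((n_voxels, n_types), (1 - purity) / (n_types - 1))
            occupancy[np.arange(n_voxels), band] = purity
    else:
        occupancy = np.full((n_voxels, n_types), 1.0 / n_types)
    counts = 1 + rng.poisson(max(mean_cells_per_voxel - 1.0, 0.0), size=n_voxels)
    placement = np.repeat(np.arange(n_voxels), counts)
    cell_types = np.concatenate([
        rng.choice(n_types, size=c, p=occupancy[j]) for j, c in enumerate(counts)
    ])
    return occupancy, placement, cell_types


def render_spatial(signatures: np.ndarray, placement: np.ndarray,
                   cell_types: np.ndarray, resolution: str = "spots",
                   poisson_rate: float = 1.0, dropout_prob: float = 0.0,
                   unit_scale: float = 1.0, seed: int = 0,
                   n_voxels: int | None = None) -> SpatialMatrix:
    """Render the spatial measurement from placed cells.

    ``single_cell``: one voxel per placed cell, mean expression = the cell's
    clean signature.  ``spots``: per voxel, the sum of resident cells'
    signatures.  The mean is then Poisson-sampled at depth ``poisson_rate``
    (0 = return the mean exactly), entries are zeroed i.i.d. with probability
    ``dropout_prob``, and the whole matrix is multiplied by ``unit_scale``.
    """
    if resolution not in ("single_cell", "spots"):
        raise ValueError(f"unknown resolution {resolution!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5ba7]))
    if resolution == "single_cell":
        mean = signatures[cell_types]
        ids = [f"sv{i}" for i in range(mean.shape[0])]
    else:
        nv = n_voxels if n_voxels is not None else int(placement.max()) + 1
        mean = np.zeros((nv, signatures.shape[1]))
        np.add.at(mean, placement, signatures[cell_types])
        ids = [f"voxel{j}" for j in range(nv)]
    if poisson_rate > 0:
        values = rng.poisson(mean * poisson_rate).astype(float) / poisson_rate
    else:
        values = mean.astype(float)
    if dropout_prob > 0:
        values = values * (rng.random(values.shape) >= dropout_prob)
    values = values * unit_scale
    gene_ids = [f"g{k}" for k in range(signatures.shape[1])]
    return SpatialMatrix(values, np.asarray(ids, dtype=object),
                         np.asarray(gene_ids, dtype=object))


def make_truth(params: SyntheticParams) -> SyntheticTruth:
    """Build the full fixture from one parameter set (bit-reproducible)."""
    streams = _streams(params.seed)
    signatures = generate_profiles(params.n_types, params.n_genes,
                                   params.markers_per_type, params.effect,
                                   seed=params.seed)
    occupancy, placement, cell_types = generate_tissue(
        params.n_voxels, params.n_types, params.layout, seed=params.seed + 1,
        mean_cells_per_voxel=params.mean_cells_per_voxel, purity=params.purity)
    n_cells = placement.size

    mean_sc = signatures[cell_types] * params.sc_depth
    if params.sc_depth > 0:
        sc_values = streams["sc"].poisson(mean_sc).astype(float)
    else:
        sc_values = signatures[cell_types].astype(float)
    type_names = [f"type{t}" for t in range(params.n_types)]
    sc = SingleCellMatrix(
        sc_values,
        cell_ids=np.asarray([f"cell{i}" for i in range(n_cells)], dtype=object),
        gene_ids=np.asarray([f"g{k}" for k in range(params.n_genes)], dtype=object),
        labels=np.asarray([type_names[t] for t in cell_types], dtype=object))

    sp = render_spatial(signatures, placement, cell_types, resolution="spots",
                        poisson_rate=params.poisson_rate,
                        dropout_prob=params.dropout_prob,
                        unit_scale=params.unit_scale, seed=params.seed + 2,
                        n_voxels=params.n_voxels)
    seg_counts = np.bincount(placement, minlength=params.n_voxels)
    return SyntheticTruth(sc=sc, sp=sp, placement=placement,
                          type_occupancy=occupancy, seg_counts=seg_counts,
                          signatures=signatures, type_names=type_names,
                          params=params)


def standard_suite(seed: int = 0, **overrides) -> SyntheticTruth:
    """The default fixture: 5 types, 200 genes (20 markers/type, effect 8),
    100 layered voxels, ~300 cells."""
    return make_truth(SyntheticParams(seed=seed, **overrides))


def voxel_true_labels(truth: SyntheticTruth) -> np.ndarray:
    """Ground-truth type per voxel: majority type among its placed cells
    (ties broken by the voxel's occupancy-dominant type)."""
    labels = np.empty(truth.params.n_voxels, dtype=object)
    cell_types = np.asarray(
        [truth.type_names.index(t) for t in truth.sc.labels])
    for j in range(truth.params.n_voxels):
        here = cell_types[truth.placement == j]
        if here.size == 0:
            labels[j] = truth.type_names[int(truth.type_occupancy[j].argmax())]
            continue
        counts = np.bincount(here, minlength=truth.params.n_types)
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        if tied.size > 1:
            dom = int(truth.type_occupancy[j].argmax())
            pick = dom if dom in tied else int(tied[0])
        else:
            pick = int(tied[0])
        labels[j] = truth.type_names[pick]
    return labels
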