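"""Gradient-based training loop learning the cell-to-voxel mapping.

Two modes:

* ``plain`` — learn only the mapping logits; every cell is mapped.
* ``filtered`` — additionally learn a per-cell filter selecting the subset of
  profiles that best explains the spatial data, with a soft count constraint
  toward ``n_target_cells``.

Optimization is full-batch Adam on the analytic gradients from
:mod:`voxmap.objective`.  Logits are initialized from seeded standard-normal
draws, so a fit is bit-reproducible from its configuration snapshot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .data_model import (DensityPrior, SingleCellMatrix, SpatialMatrix,
                         density_from_segmentation, uniform_density)
from .objective import LossBreakdown, LossWeights, loss_and_grads, sigmoid_filter, softmax_rows

logger = logging.getLogger(__name__)

__all__ = ["MappingResult", "FitConfig", "fit", "mode_targeted", "mode_deconvolution",
           "DEFAULT_EPOCHS"]

# per-use-case epoch defaults (targeted in situ data; probabilistic spot
# mapping; spot deconvolution; coarse atlas-style mapping)
DEFAULT_EPOCHS = {"targeted": 1200, "spots": 300, "deconvolution": 6000, "atlas": 150}


@dataclass(frozen=True)
class FitConfig:
    """Resolved settings of one fit; stored in the result for reproducibility."""

    mode: str = "plain"
    n_target_cells: int | None = None
    epochs: int = 1000
    learning_rate: float = 0.1
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    lambda_entropy: float = 0.0

    def as_dict(self) -> dict[str, Any]:
        out = asdict(self)
        out["weights"] = asdict(self.weights)
        return out


@dataclass
class MappingResult:
    """Learned mapping: row-stochastic ``M``, optional filter ``f``, loss trace."""

    M: np.ndarray
    cell_ids: np.ndarray
    voxel_ids: np.ndarray
    f: np.ndarray | None
    loss_trace: list[LossBreakdown]
    config: FitConfig

    @property
    def n_cells(self) -> int:
        return self.M.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.M.shape[1]

    def sharpness(self) -> float:
        """Fraction of (retained) cells whose maximal voxel probability
        exceeds 0.5 — the convergence statistic reported for inspection."""
        M = self.M
        if self.f is not None:
            keep = self.f > 0.5
            if not keep.any():
                return float("nan")
            M = M[keep]
        return float((M.max(axis=1) > 0.5).mean())


def _adam_step(param, grad, state, lr, beta1=0.9, beta2=0.999, eps=1e-8):
    state["t"] += 1
    t = state["t"]
    state["m"] = beta1 * state["m"] + (1 - beta1) * grad
    state["v"] = beta2 * state["v"] + (1 - beta2) * grad * grad
    m_hat = state["m"] / (1 - beta1**t)
    v_hat = state["v"] / (1 - beta2**t)
    return param - lr * m_hat / (np.sqrt(v_hat) + eps)


def fit(sc: SingleCellMatrix, sp: SpatialMatrix, density: DensityPrior,
        mode: str = "plain", n_target_cells: int | None = None,
        epochs: int = 1000, learning_rate: float = 0.1, seed: int = 0,
        weights: LossWeights = LossWeights(), lambda_entropy: float = 0.0,
        log_every: int = 100) -> MappingResult:
    """Learn the mapping by minimizing the composite objective.

    ``sc`` and ``sp`` must already be restricted to the same ordered training
    gene panel (see :func:`voxmap.data_model.intersect_genes`).  With
    ``epochs=0`` the returned ``M`` is the softmax of the random
    initialization — still row-stochastic by construction.
    """
    if mode not in ("plain", "filtered"):
        raise ValueError(f"unknown mode {mode!r}")
    if not np.array_equal(sc.gene_ids, sp.gene_ids):
        raise ValueError("sc and sp must share an identical ordered gene panel")
    if density.n_voxels != sp.n_voxels:
        raise ValueError("density length must equal n_voxels")
    filtered = mode == "filtered"
    if filtered:
        if n_target_cells is None:
            raise ValueError("filtered mode requires n_target_cells")
        if n_target_cells > sc.n_cells:
            raise ValueError(
                f"n_target_cells ({n_target_cells}) exceeds n_cells ({sc.n_cells})")

    config = FitConfig(mode=mode, n_target_cells=n_target_cells if filtered else None,
                       epochs=epochs, learning_rate=learning_rate, seed=seed,
                       weights=weights, lambda_entropy=lambda_entropy)

    rng = np.random.default_rng(seed)
    m_tilde = rng.standard_normal((sc.n_cells, sp.n_voxels))
    f_tilde = rng.standard_normal(sc.n_cells) if filtered else None

    S, G, d = sc.values, sp.values, density.d
    state_m = {"t": 0, "m": np.zeros_like(m_tilde), "v": np.zeros_like(m_tilde)}
    state_f = ({"t": 0, "m": np.zeros(sc.n_cells), "v": np.zeros(sc.n_cells)}
               if filtered else None)

    trace: list[LossBreakdown] = []
    for epoch in range(epochs):
        breakdown, grad_mt, grad_ft = loss_and_grads(
            m_tilde, f_tilde, S, G, d, weights, lambda_entropy,
            n_target_cells if filtered else None)
        if not np.isfinite(breakdown.total):
            bad = [k for k, v in breakdown.as_dict().items() if not np.isfinite(v)]
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}; offending term(s): {bad}")
        trace.append(breakdown)
        if log_every and epoch % log_every == 0:
            logger.info("epoch %d: total=%.6f density=%.6f gene=%.6f voxel=%.6f",
                        epoch, breakdown.total, breakdown.density_term,
                        breakdown.gene_axis_term, breakdown.voxel_axis_term)
        m_tilde = _adam_step(m_tilde, grad_mt, state_m, learning_rate)
        if filtered:
            f_tilde = _adam_step(f_tilde, grad_ft, state_f, learning_rate)

    # final loss at the returned parameters
    final, _, _ = loss_and_grads(m_tilde, f_tilde, S, G, d, weights,
                                 lambda_entropy,
                                 n_target_cells if filtered else None,
                                 compute_grads=False)
    trace.append(final)

    return MappingResult(M=softmax_rows(m_tilde), cell_ids=sc.cell_ids,
                         voxel_ids=sp.voxel_ids,
                         f=sigmoid_filter(f_tilde) if filtered else None,
                         loss_trace=trace, config=config)


def mode_targeted(sc: SingleCellMatrix, sp: SpatialMatrix) -> dict[str, Any]:
    """Fit configuration for single-cell-resolution spatial data.

    Voxels are individual cells in space, so the density prior is uniform.
    When single-cell profiles outnumber voxels the filtered objective selects
    exactly ``n_voxels`` of them; otherwise every profile is mapped with the
    plain objective.
    """
    if sc.n_cells >= sp.n_voxels:
        return {"mode": "filtered", "n_target_cells": sp.n_voxels,
                "density": uniform_density(sp.n_voxels)}
    return {"mode": "plain", "density": uniform_density(sp.n_voxels)}


def mode_deconvolution(sc: SingleCellMatrix, sp: SpatialMatrix,
                       seg_counts) -> dict[str, Any]:
    """Fit configuration for deconvolving multi-cell spots.

    Uses the segmentation-derived density prior and targets the total number
    of segmented cells, so the count and density terms jointly push the
    expected number of cells into each spot.
    """
    seg_counts = np.asarray(seg_counts)
    n_seg = int(seg_counts.sum())
    if n_seg > sc.n_cells:
        raise ValueError(
            f"total segmented cells ({n_seg}) exceeds available profiles ({sc.n_cells})")
    return {"mode": "filtered", "n_target_cells": n_seg,
            "density": density_from_segmentation(seg_counts)}
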