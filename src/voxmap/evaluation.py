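"""Holdout-gene validation of learned mappings.

The mapping is trained on a gene panel and judged by how well it predicts the
spatial pattern of genes it never saw: each held-out gene's predicted
per-voxel profile (``M^T S`` restricted to that gene) is compared with its
measurement by Pearson correlation across voxels ("spatial correlation").
Drivers here cover leave-one-out over a panel, a single train/test partition,
and a sweep over training-panel fractions; summaries stratify scores by the
gene's measurement sparsity (fraction of voxels where it is undetected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DensityPrior, SingleCellMatrix, SpatialMatrix, \
    compute_sparsity, intersect_genes
from .mapper import fit
from .transfer import project_genes

__all__ = ["GeneScoreTable", "spatial_correlation", "holdout_scores",
           "leave_one_out", "train_test_partition", "training_fraction_sweep",
           "score_quantiles", "sparsity_stratified_summary"]


@dataclass
class GeneScoreTable:
    """Per-gene validation scores.

    ``table`` columns: gene, score (spatial correlation in [-1, 1], NaN when
    undefined), split ("train"/"test"), sparsity (measured), pred_sparsity.
    ``metadata`` records scoring choices (correlation method, normalization).
    """

    table: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def subset(self, split: str | None = None,
               max_sparsity: float | None = None) -> pd.DataFrame:
        t = self.table
        if split is not None:
            t = t[t["split"] == split]
        if max_sparsity is not None:
            t = t[t["sparsity"] < max_sparsity]
        return t


def spatial_correlation(pred, meas, method: str = "pearson") -> float:
    """Correlation across voxels between predicted and measured profiles.

    Returns NaN (flagged undefined) when either vector is constant.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape:
        raise ValueError("length mismatch")
    if pred.size < 2:
        raise ValueError("need at least 2 voxels")
    if np.std(pred) == 0 or np.std(meas) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(pred, meas)[0])
    if method == "spearman":
        return float(stats.spearmanr(pred, meas)[0])
    raise ValueError(f"unknown method {method!r}")


def _score_genes(pred_df: pd.DataFrame, sp: SpatialMatrix, genes: list[str],
                 split: str, sparsity: dict[str, float],
                 method: str) -> list[dict]:
    meas = sp.to_frame()
    rows = []
    for g in genes:
        p = pred_df[g].to_numpy()
        m = meas[g].to_numpy()
        rows.append({
            "gene": g,
            "score": spatial_correlation(p, m, method=method),
            "split": split,
            "sparsity": sparsity[g],
            "pred_sparsity": float((p == 0).mean()),
        })
    return rows


def train_test_partition(all_genes, panel) -> tuple[list[str], list[str]]:
    """Split genes into the training panel and the held-out remainder."""
    panel_set = set(panel)
    missing = panel_set - set(all_genes)
    if missing:
        raise ValueError(f"panel genes absent from gene list: {sorted(missing)[:5]}")
    train = list(panel)
    test = [g for g in all_genes if g not in panel_set]
    return train, test


def holdout_scores(sc: SingleCellMatrix, sp: SpatialMatrix, density: DensityPrior,
                   panel: list[str], method: str = "pearson",
                   **fit_kwargs) -> GeneScoreTable:
    """Fit on ``panel``, impute every shared gene, score train and test genes.

    Test genes are all genes shared by the two modalities but absent from the
    panel.  Sparsity is taken from the spatial measurement as given.
    """
    sc_shared, sp_shared = intersect_genes(sc, sp)
    train, test = train_test_partition(list(sp_shared.gene_ids), panel)
    sc_train, sp_train = intersect_genes(sc, sp, panel=train)
    result = fit(sc_train, sp_train, density, **fit_kwargs)
    pred = project_genes(result, sc_shared).to_frame()
    sparsity = dict(zip(sp_shared.gene_ids, compute_sparsity(sp_shared)))
    rows = _score_genes(pred, sp_shared, train, "train", sparsity, method)
    rows += _score_genes(pred, sp_shared, test, "test", sparsity, method)
    return GeneScoreTable(pd.DataFrame(rows),
                          metadata={"method": method, "n_train": len(train),
                                    "n_test": len(test),
                                    "fit": {k: v for k, v in fit_kwargs.items()
                                            if k != "weights"}})


def leave_one_out(sc: SingleCellMatrix, sp: SpatialMatrix, density: DensityPrior,
                  panel: list[str], method: str = "pearson",
                  **fit_kwargs) -> GeneScoreTable:
    """Leave-one-out validation over a gene panel.

    For each gene g, refit on panel minus g (same init seed per fold for
    comparability), impute g via the learned mapping, and score it against
    the measurement.  One fit per panel gene.
    """
    if len(panel) < 2:
        raise ValueError("leave-one-out needs a panel of at least 2 genes")
    sc_panel, sp_panel = intersect_genes(sc, sp, panel=panel)
    sparsity = dict(zip(sp_panel.gene_ids, compute_sparsity(sp_panel)))
    rows = []
    for g in panel:
        rest = [x for x in panel if x != g]
        sc_train, sp_train = intersect_genes(sc, sp, panel=rest)
        try:
            result = fit(sc_train, sp_train, density, **fit_kwargs)
        except Exception as err:
            raise RuntimeError(f"fit failed while holding out gene {g!r}") from err
        pred = project_genes(result, sc_panel).to_frame()
        rows += _score_genes(pred, sp_panel, [g], "test", sparsity, method)
    return GeneScoreTable(pd.DataFrame(rows),
                          metadata={"method": method, "strategy": "leave-one-out",
                                    "n_folds": len(panel)})


def training_fraction_sweep(sc: SingleCellMatrix, sp: SpatialMatrix,
                            density: DensityPrior, panel: list[str],
                            fractions, seed: int = 0, method: str = "pearson",
                            **fit_kwargs) -> pd.DataFrame:
    """Prediction performance as the training panel shrinks.

    For each fraction, a seeded uniform subsample of the panel is used for
    training.  The test set is fixed across fractions — the shared complement
    of the *full* panel — so score changes reflect training-set size, not a
    shifting test-gene composition.  Reports mean train score, mean test
    score, and the test score scaled by the mean train score.
    """
    rng = np.random.default_rng(seed)
    sc_shared, sp_shared = intersect_genes(sc, sp)
    all_genes = list(sp_shared.gene_ids)
    _, base_test = train_test_partition(all_genes, panel)
    out = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        n_sub = int(round(frac * len(panel)))
        if n_sub < 2:
            import warnings
            warnings.warn(f"fraction {frac} yields < 2 training genes; skipped")
            continue
        if frac == 1:
            sub = list(panel)
        else:
            sub = sorted(rng.choice(panel, size=n_sub, replace=False))
        test = base_test
        sc_train, sp_train = intersect_genes(sc, sp, panel=sub)
        result = fit(sc_train, sp_train, density, **fit_kwargs)
        pred = project_genes(result, sc_shared).to_frame()
        sparsity = dict(zip(sp_shared.gene_ids, compute_sparsity(sp_shared)))
        train_scores = pd.DataFrame(
            _score_genes(pred, sp_shared, sub, "train", sparsity, method))["score"]
        test_scores = pd.DataFrame(
            _score_genes(pred, sp_shared, test, "test", sparsity, method))["score"]
        mean_train = float(np.nanmean(train_scores))
        mean_test = float(np.nanmean(test_scores))
        out.append({"fraction": frac, "n_train": n_sub,
                    "mean_train_score": mean_train, "mean_test_score": mean_test,
                    "scaled_test_score": mean_test / mean_train
                    if mean_train != 0 else float("nan")})
    return pd.DataFrame(out)


def score_quantiles(scores: GeneScoreTable, q: float,
                    split: str | None = None) -> float:
    """Empirical quantile (linear interpolation) of the chosen score subset."""
    t = scores.subset(split=split)
    vals = t["score"].dropna()
    if vals.empty:
        raise ValueError("empty score subset")
    return float(np.quantile(vals, q))


def sparsity_stratified_summary(scores: GeneScoreTable, threshold: float,
                                sparse_cutoff: float = 0.5) -> dict[str, int]:
    """Count genes in three performance regions.

    (i) non-sparse (sparsity < cutoff) and score >= threshold — well
    predicted; (ii) non-sparse below threshold — poorly predicted despite
    dense measurement; (iii) sparse (sparsity >= cutoff) — measurement too
    sparse to judge.
    """
    t = scores.table
    if t.empty:
        raise ValueError("empty score table")
    sparse = t["sparsity"] >= sparse_cutoff
    above = t["score"] >= threshold
    return {
        "nonsparse_above": int((~sparse & above).sum()),
        "nonsparse_below": int((~sparse & ~above).sum()),
        "sparse": int(sparse.sum()),
    }
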