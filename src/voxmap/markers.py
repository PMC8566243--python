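"""Training-panel selection from differentially expressed marker genes.

The training panel is the union of the top-k marker genes of each cell type,
where markers are ranked by a Welch (unequal-variance) t statistic of the
type's cells against all other cells.  Ranking is computed on library-size
normalized, log1p-transformed, per-gene standardized expression; the
standardization happens internally so the container's non-negativity
invariant is never violated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SingleCellMatrix, SpatialMatrix

__all__ = ["MarkerRanking", "rank_markers", "training_panel"]


@dataclass(frozen=True)
class MarkerRanking:
    """Per-type marker ranking: a tidy frame with columns
    (cell_type, rank, gene, statistic), sorted by descending statistic within
    each type; ties broken lexicographically by gene id."""

    table: pd.DataFrame

    def top(self, cell_type: str, k: int) -> list[str]:
        sub = self.table[self.table["cell_type"] == cell_type]
        return list(sub.sort_values("rank")["gene"].head(k))

    @property
    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.table["cell_type"]))


def rank_markers(sc: SingleCellMatrix, standardize: bool = True) -> MarkerRanking:
    """Rank genes per cell type by Welch t statistic, type vs. rest.

    The statistic is signed and two-sided in form, but ranking by the signed
    value means genes upregulated in the type rank first.  Genes with zero
    variance in both groups get statistic 0 (a tie).  ``standardize`` z-scores
    each gene across cells before testing.
    """
    if sc.labels is None:
        raise ValueError("rank_markers requires cell labels")
    labels = np.asarray(sc.labels)
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")

    X = sc.values
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    rows = []
    for t in types:
        in_group = labels == t
        if in_group.sum() < 2 or (~in_group).sum() < 2:
            raise ValueError(f"cell type {t!r} needs >= 2 cells in each group")
        with np.errstate(divide="ignore", invalid="ignore"):
            stat, _ = stats.ttest_ind(X[in_group], X[~in_group], equal_var=False)
        stat = np.nan_to_num(np.asarray(stat), nan=0.0)
        order = sorted(range(sc.n_genes), key=lambda g: (-stat[g], sc.gene_ids[g]))
        for rank, g in enumerate(order, start=1):
            rows.append((t, rank, sc.gene_ids[g], float(stat[g])))
    table = pd.DataFrame(rows, columns=["cell_type", "rank", "gene", "statistic"])
    return MarkerRanking(table)


def training_panel(ranking: MarkerRanking, k: int, sp: SpatialMatrix) -> list[str]:
    """Union of each type's top-k markers, restricted to the spatial genes.

    Order is deterministic: first appearance, iterating types in ranking
    order with ranks ascending within each type.  The conventional default in
    the pipeline is k=100 markers per type.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sp_genes = set(sp.gene_ids)
    panel: list[str] = []
    seen: set[str] = set()
    for t in ranking.cell_types:
        for g in ranking.top(t, k):
            if g in sp_genes and g not in seen:
                panel.append(g)
                seen.add(g)
    if not panel:
        raise ValueError("empty training panel after spatial-gene restriction")
    return panel
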