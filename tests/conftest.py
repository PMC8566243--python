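"""Shared fixtures: identity/self-mapping problems and the standard synthetic suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import voxmap as vm
from voxmap.objective import loss


def make_self_mapping(n, n_genes=None, seed=42):
    """Self-mapping fixture: n cells with distinct random profiles, G = S
    shuffled by a known permutation (voxel j holds the cell with
    perm[i] == j), uniform density."""
    rng = np.random.default_rng(seed)
    n_genes = n_genes or 2 * n
    S = rng.uniform(0.5, 5.0, (n, n_genes))
    perm = rng.permutation(n)
    G = S[np.argsort(perm)]
    sc = vm.SingleCellMatrix(S, [f"c{i}" for i in range(n)],
                             [f"g{k}" for k in range(n_genes)])
    sp = vm.SpatialMatrix(G, [f"v{j}" for j in range(n)],
                          [f"g{k}" for k in range(n_genes)])
    return sc, sp, vm.uniform_density(n), tuple(int(p) for p in perm)


def brute_force_best_permutation(S, G, d):
    """Enumerate all n! hard assignments of the plain objective and return
    the loss-minimizing permutation (cell i -> voxel perm[i])."""
    n = S.shape[0]
    best_total, best_perm = np.inf, None
    for perm in itertools.permutations(range(n)):
        m_tilde = np.full((n, n), -200.0)
        m_tilde[np.arange(n), perm] = 200.0
        total = loss(m_tilde, None, S, G, np.asarray(d)).total
        if total < best_total:
            best_total, best_perm = total, perm
    return best_perm, best_total


def brute_force_best_subset(S, G, d, n_target):
    """Enumerate all C(n_cells, n_target) subsets x n_target! assignments of
    the filtered objective; return (subset, perm, total) at the minimum."""
    n_cells, n_voxels = S.shape[0], G.shape[0]
    best = (np.inf, None, None)
    for subset in itertools.combinations(range(n_cells), n_target):
        for perm in itertools.permutations(range(n_voxels)):
            m_tilde = np.zeros((n_cells, n_voxels))
            f_tilde = np.full(n_cells, -200.0)
            for c, j in zip(subset, perm):
                m_tilde[c] = -200.0
                m_tilde[c, j] = 200.0
                f_tilde[c] = 200.0
            total = loss(m_tilde, f_tilde, S, G, np.asarray(d),
                         n_target_cells=n_target).total
            if total < best[0]:
                best = (total, subset, perm)
    return best[1], best[2], best[0]


def make_planted_filter_fixture(seed=7):
    """6 cells / 3 voxels: cells 0-2 exactly produce the 3 voxel profiles,
    cells 3-5 express disjoint (orthogonal) gene blocks."""
    rng = np.random.default_rng(seed)
    n_genes = 12
    planted = np.zeros((3, n_genes))
    distract = np.zeros((3, n_genes))
    for i in range(3):
        planted[i, 4 * i:4 * i + 2] = rng.uniform(2, 5, 2)
        distract[i, 4 * i + 2:4 * i + 4] = rng.uniform(2, 5, 2)
    S = np.vstack([planted, distract])
    G = planted.copy()
    sc = vm.SingleCellMatrix(S, [f"c{i}" for i in range(6)],
                             [f"g{k}" for k in range(n_genes)])
    sp = vm.SpatialMatrix(G, [f"v{j}" for j in range(3)],
                          [f"g{k}" for k in range(n_genes)])
    return sc, sp, vm.uniform_density(3)


@pytest.fixture(scope="session")
def suite():
    """Standard synthetic suite: 5 types, 200 genes, 100 layered voxels,
    ~300 cells, seed 0."""
    return vm.standard_suite(seed=0)


@pytest.fixture(scope="session")
def suite_panel(suite):
    """Marker-derived training panel (top 10 per type) for the suite."""
    sc_n = vm.log1p_transform(vm.normalize_library_size(suite.sc))
    ranking = vm.rank_markers(sc_n)
    return vm.training_panel(ranking, 10, suite.sp)


@pytest.fixture(scope="session")
def suite_fit(suite, suite_panel):
    """Plain-mode fit of the suite on its marker panel (segmentation density)."""
    sc_t, sp_t = vm.intersect_genes(suite.sc, suite.sp, panel=suite_panel)
    d = vm.density_from_segmentation(suite.seg_counts)
    return vm.fit(sc_t, sp_t, d, mode="plain", epochs=300, seed=0)
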