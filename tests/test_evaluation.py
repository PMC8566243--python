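import numpy as np
import pytest

import voxmap as vm
from voxmap.evaluation import GeneScoreTable
from voxmap.mapper import FitConfig, MappingResult
import pandas as pd


class TestSpatialCorrelation:
    def test_perfect_and_inverted(self):
        x = np.array([1.0, 2.0, 5.0])
        assert vm.spatial_correlation(x, x) == pytest.approx(1.0)
        assert vm.spatial_correlation(x, -x + 10) == pytest.approx(-1.0)

    def test_against_independent_routine(self):
        pred, meas = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        expected = np.corrcoef(pred, meas)[0, 1]
        assert vm.spatial_correlation(pred, meas) == pytest.approx(expected,
                                                                   abs=1e-12)
        assert expected == pytest.approx(0.98198, abs=1e-5)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=30), rng.normal(size=30)
        base = vm.spatial_correlation(a, b)
        assert vm.spatial_correlation(3 * a + 7, b) == pytest.approx(base, abs=1e-9)
        assert vm.spatial_correlation(a, 0.1 * b - 2) == pytest.approx(base,
                                                                       abs=1e-9)

    def test_zero_variance_flagged_undefined(self):
        assert np.isnan(vm.spatial_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            vm.spatial_correlation([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPartition:
    def test_split_counts(self):
        genes = [f"g{k}" for k in range(10)]
        train, test = vm.train_test_partition(genes, genes[:3])
        assert train == genes[:3] and len(test) == 7

    def test_full_panel_empty_test(self):
        genes = ["a", "b"]
        _, test = vm.train_test_partition(genes, genes)
        assert test == []

    def test_panel_outside_gene_list_rejected(self):
        with pytest.raises(ValueError):
            vm.train_test_partition(["a", "b"], ["a", "z"])


def perfect_oracle_scores(suite):
    """Score genes with the mapping fixed to ground truth (cell i -> its true
    voxel), isolating the scoring path from optimization."""
    n_cells = suite.sc.n_cells
    M = np.zeros((n_cells, suite.params.n_voxels))
    M[np.arange(n_cells), suite.placement] = 1.0
    result = MappingResult(M=M, cell_ids=suite.sc.cell_ids,
                           voxel_ids=suite.sp.voxel_ids, f=None,
                           loss_trace=[], config=FitConfig())
    return vm.project_genes(result, suite.sc).to_frame()


class TestLeaveOneOut:
    def test_oracle_mapping_scores_near_one_noiseless(self):
        """With a noiseless fixture and the ground-truth mapping injected, every
        marker gene scores ~1 (no optimization involved)."""
        truth = vm.standard_suite(seed=1, poisson_rate=0.0, sc_depth=0.0)
        pred = perfect_oracle_scores(truth)
        meas = truth.sp.to_frame()
        for g in ["g0", "g25", "g45", "g65", "g85"]:  # one marker per type
            r = vm.spatial_correlation(pred[g].to_numpy(), meas[g].to_numpy())
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_driver_runs_one_fit_per_gene(self):
        sc, sp, d, _ = _small_identity(6)
        scores = vm.leave_one_out(sc, sp, d, ["g0", "g1"], epochs=50, seed=0)
        assert len(scores.table) == 2
        assert set(scores.table["gene"]) == {"g0", "g1"}

    def test_held_out_zero_gene_flagged(self):
        sc, sp, d, _ = _small_identity(5)
        vals = sp.values.copy()
        vals[:, 2] = 0.0
        sp2 = vm.SpatialMatrix(vals, sp.voxel_ids, sp.gene_ids)
        scores = vm.leave_one_out(sc, sp2, d, ["g0", "g1", "g2"], epochs=50, seed=0)
        assert np.isnan(scores.table.set_index("gene").loc["g2", "score"])


def _small_identity(n):
    from conftest import make_self_mapping
    return make_self_mapping(n, n_genes=8, seed=17)


class TestSweep:
    def test_fraction_one_reproduces_base_partition(self, suite, suite_panel):
        d = vm.density_from_segmentation(suite.seg_counts)
        sweep = vm.training_fraction_sweep(suite.sc, suite.sp, d,
                                           suite_panel[:12], fractions=[1.0],
                                           seed=0, epochs=100)
        base = vm.holdout_scores(suite.sc, suite.sp, d, suite_panel[:12],
                                 epochs=100, seed=0)
        assert sweep.loc[0, "mean_train_score"] == pytest.approx(
            float(np.nanmean(base.subset(split="train")["score"])), abs=1e-12)

    def test_identical_seeds_identical_subsamples(self, suite, suite_panel):
        d = vm.density_from_segmentation(suite.seg_counts)
        kw = dict(fractions=[0.5], seed=4, epochs=60)
        s1 = vm.training_fraction_sweep(suite.sc, suite.sp, d, suite_panel[:12], **kw)
        s2 = vm.training_fraction_sweep(suite.sc, suite.sp, d, suite_panel[:12], **kw)
        assert s1.equals(s2)

    def test_tiny_fraction_skipped_with_warning(self, suite, suite_panel):
        d = vm.density_from_segmentation(suite.seg_counts)
        with pytest.warns(UserWarning, match="skipped"):
            sweep = vm.training_fraction_sweep(suite.sc, suite.sp, d,
                                               suite_panel[:12],
                                               fractions=[0.05, 1.0], seed=0,
                                               epochs=60)
        assert list(sweep["fraction"]) == [1.0]


class TestSummaries:
    def _table(self, scores, sparsity=None):
        n = len(scores)
        sparsity = sparsity if sparsity is not None else [0.0] * n
        return GeneScoreTable(pd.DataFrame({
            "gene": [f"g{k}" for k in range(n)], "score": scores,
            "split": ["train"] * n, "sparsity": sparsity,
            "pred_sparsity": [0.0] * n}))

    def test_quantile_within_order_statistic_bounds(self):
        t = self._table([k / 10 for k in range(1, 11)])
        q = vm.score_quantiles(t, 0.9)
        assert 0.9 <= q <= 1.0

    def test_quantile_empty_subset_errors(self):
        t = self._table([np.nan, np.nan])
        with pytest.raises(ValueError):
            vm.score_quantiles(t, 0.5)

    def test_region_partition(self):
        t = self._table([0.9, 0.2, 0.5], sparsity=[0.1, 0.2, 0.8])
        regions = vm.sparsity_stratified_summary(t, threshold=0.4)
        assert regions == {"nonsparse_above": 1, "nonsparse_below": 1, "sparse": 1}

    def test_all_dense_no_sparse_region(self):
        t = self._table([0.9, 0.8])
        assert vm.sparsity_stratified_summary(t, 0.4)["sparse"] == 0

    def test_threshold_above_max_empties_top_region(self):
        t = self._table([0.3, 0.2])
        assert vm.sparsity_stratified_summary(t, 0.99)["nonsparse_above"] == 0
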