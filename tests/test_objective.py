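"""Oracle checks for every loss term and the analytic gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voxmap.objective import (LossWeights, cosine_terms, count_and_filter_terms,
                              entropy_regularizer, kl_divergence, loss,
                              loss_and_grads, predicted_density, sigmoid_filter,
                              softmax_rows)


class TestSoftmaxSigmoid:
    def test_closed_forms(self):
        np.testing.assert_allclose(softmax_rows(np.array([[0.0, 0.0]])), [[0.5, 0.5]])
        np.testing.assert_allclose(softmax_rows(np.array([[np.log(3), 0.0]])),
                                   [[0.75, 0.25]])

    def test_stabilized_against_overflow(self):
        out = softmax_rows(np.array([[1000.0, 0.0]]))
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out, [[1.0, 0.0]], atol=1e-12)

    def test_rows_sum_to_one_random(self):
        rng = np.random.default_rng(0)
        M = softmax_rows(rng.standard_normal((1000, 7)) * 10)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-6)

    def test_sigmoid_symmetry(self):
        f = sigmoid_filter(np.array([0.0, 50.0, -3.0, 3.0]))
        assert f[0] == 0.5 and f[1] > 1 - 1e-12
        np.testing.assert_allclose(f[2], 1 - f[3], atol=1e-12)


class TestPredictedDensity:
    def test_unfiltered_mean_of_rows(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(predicted_density(M), [0.5, 0.5])

    def test_conservation(self):
        M = softmax_rows(np.random.default_rng(1).standard_normal((9, 5)))
        assert abs(predicted_density(M).sum() - 1.0) < 1e-12

    def test_filtered_single_survivor(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(predicted_density(M, f=np.array([1.0, 0.0])),
                                   [1.0, 0.0])
        with pytest.raises(ValueError):
            predicted_density(M, f=np.array([0.0, 0.0]))


class TestKL:
    def test_identity_is_zero(self):
        d = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(d, d) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # 0.5*ln(0.5/0.25) + 0.5*ln(0.5/0.75) = 0.5*ln2 + 0.5*ln(2/3)
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert kl_divergence(np.array([0.5, 0.5]), np.array([0.25, 0.75])) == \
            pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.14384, abs=1e-5)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_nonnegative_on_random_simplex_pairs(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 10)
        m, d = rng.dirichlet(np.ones(k)), rng.dirichlet(np.ones(k))
        assert kl_divergence(m, d) >= -1e-9

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kl_divergence(np.array([1.0]), np.array([0.5, 0.5]))


class TestCosineTerms:
    def test_perfect_prediction_is_maximal(self):
        rng = np.random.default_rng(3)
        S = rng.uniform(0.1, 2, (4, 6))
        M = np.eye(4)
        G = S.copy()
        g, v = cosine_terms(M, S, G)
        assert g == pytest.approx(6.0, abs=1e-9)
        assert v == pytest.approx(4.0, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        M = softmax_rows(rng.standard_normal((5, 3)))
        S = rng.uniform(0.1, 2, (5, 7))
        G = rng.uniform(0.1, 2, (3, 7))
        base = cosine_terms(M, S, G)
        np.testing.assert_allclose(cosine_terms(M, S * 13.7, G), base, atol=1e-9)
        np.testing.assert_allclose(cosine_terms(M, S, G * 0.003), base, atol=1e-9)

    def test_single_gene_closed_form(self):
        M = np.eye(2)
        S = np.array([[1.0], [1.0]])
        G = np.array([[1.0], [0.0]])
        g, _ = cosine_terms(M, S, G)
        assert g == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_zero_vector_contributes_zero(self):
        M = np.eye(2)
        S = np.array([[0.0, 1.0], [0.0, 1.0]])
        G = np.array([[1.0, 1.0], [1.0, 1.0]])
        g, v = cosine_terms(M, S, G)
        assert np.isfinite(g) and np.isfinite(v)


class TestRegularizers:
    def test_entropy_bounds(self):
        one_hot = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert entropy_regularizer(one_hot) == pytest.approx(0.0, abs=1e-6)
        uniform = np.full((1, 8), 1 / 8)
        assert entropy_regularizer(uniform) == pytest.approx(np.log(8), abs=1e-9)

    def test_entropy_decreases_when_sharpened(self):
        rows = [softmax_rows(np.array([[t, 0.0, 0.0]])) for t in (0.0, 1.0, 3.0, 9.0)]
        ents = [entropy_regularizer(r) for r in rows]
        assert all(a > b for a, b in zip(ents, ents[1:]))

    def test_count_and_filter_extremes(self):
        f = np.array([1.0, 1.0, 0.0, 0.0])
        assert count_and_filter_terms(f, 2) == (0.0, 0.0)
        f = np.full(4, 0.5)
        c, r = count_and_filter_terms(f, 2)
        assert (c, r) == (0.0, 1.0)
        assert count_and_filter_terms(np.zeros(4), 3) == (3.0, 0.0)


class TestLossComposition:
    def test_identity_fixture_totals(self):
        # G = S, 2 distinct cells/voxels, uniform density, M = identity
        S = np.array([[5.0, 0.0, 1.0], [0.0, 4.0, 1.0]])
        m_tilde = np.array([[200.0, -200.0], [-200.0, 200.0]])
        b = loss(m_tilde, None, S, S, np.array([0.5, 0.5]))
        assert b.density_term == pytest.approx(0.0, abs=1e-9)
        assert b.gene_axis_term == pytest.approx(3.0, abs=1e-9)
        assert b.voxel_axis_term == pytest.approx(2.0, abs=1e-9)
        assert b.total == pytest.approx(-(3 + 2), abs=1e-8)

    def test_uniform_rows_worse_than_permutation(self):
        S = np.array([[5.0, 0.0, 1.0], [0.0, 4.0, 1.0]])
        perm = loss(np.array([[200.0, -200.0], [-200.0, 200.0]]), None, S, S,
                    np.array([0.5, 0.5]))
        unif = loss(np.zeros((2, 2)), None, S, S, np.array([0.5, 0.5]))
        assert unif.total > perm.total

    def test_breakdown_total_consistent(self):
        rng = np.random.default_rng(8)
        w = LossWeights(density=2.0, gene_axis=0.5, voxel_axis=1.5)
        b = loss(rng.standard_normal((4, 3)), rng.standard_normal(4),
                 rng.uniform(0.1, 1, (4, 6)), rng.uniform(0.1, 1, (3, 6)),
                 rng.dirichlet(np.ones(3)), weights=w, lambda_entropy=0.3,
                 n_target_cells=2)
        recomputed = (2.0 * b.density_term - 0.5 * b.gene_axis_term
                      - 1.5 * b.voxel_axis_term + 0.3 * b.entropy_term
                      + b.count_term + b.filter_reg_term)
        assert b.total == pytest.approx(recomputed, abs=1e-9)

    def test_filtered_mode_requires_target(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="n_target_cells"):
            loss(rng.standard_normal((3, 2)), rng.standard_normal(3),
                 rng.uniform(0.1, 1, (3, 4)), rng.uniform(0.1, 1, (2, 4)),
                 np.array([0.5, 0.5]))


class TestGradients:
    """Analytic gradients vs central finite differences (1e-4 relative)."""

    @pytest.mark.parametrize("filtered,lam", [(False, 0.0), (False, 0.5),
                                              (True, 0.0), (True, 0.5)])
    def test_matches_central_differences(self, filtered, lam):
        rng = np.random.default_rng(10)
        n_cells, n_voxels, n_genes = 3, 3, 4
        mt = rng.standard_normal((n_cells, n_voxels))
        ft = rng.standard_normal(n_cells) if filtered else None
        S = rng.uniform(0.1, 2, (n_cells, n_genes))
        G = rng.uniform(0.1, 2, (n_voxels, n_genes))
        d = rng.dirichlet(np.ones(n_voxels))
        kwargs = dict(lambda_entropy=lam,
                      n_target_cells=2 if filtered else None)
        _, gm, gf = loss_and_grads(mt, ft, S, G, d, **kwargs)

        h = 1e-6

        def total(mt_, ft_):
            return loss_and_grads(mt_, ft_, S, G, d, compute_grads=False,
                                  **kwargs)[0].total

        num_m = np.zeros_like(mt)
        for i in range(n_cells):
            for j in range(n_voxels):
                e = np.zeros_like(mt)
                e[i, j] = h
                num_m[i, j] = (total(mt + e, ft) - total(mt - e, ft)) / (2 * h)
        scale = max(np.abs(num_m).max(), 1e-12)
        assert np.abs(num_m - gm).max() / scale < 1e-4

        if filtered:
            num_f = np.zeros(n_cells)
            for i in range(n_cells):
                e = np.zeros(n_cells)
                e[i] = h
                num_f[i] = (total(mt, ft + e) - total(mt, ft - e)) / (2 * h)
            scale = max(np.abs(num_f).max(), 1e-12)
            assert np.abs(num_f - gf).max() / scale < 1e-4
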