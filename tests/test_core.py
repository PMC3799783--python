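import numpy as np
import pytest

from apca import (
    APCAParams,
    ExpressionMatrix,
    apca,
    class_stats,
    decompose,
    factor_loadings,
    gene_scores,
    gram_project,
    pca_baseline,
    score_table,
    weighted_covariance,
)


def assert_columns_match_up_to_sign(a, b, atol=1e-8):
    assert a.shape == b.shape
    for j in range(a.shape[1]):
        d = min(np.abs(a[:, j] - b[:, j]).max(),
                np.abs(a[:, j] + b[:, j]).max())
        assert d < atol


class TestGramProject:
    def test_toy_matrix_eigenstructure(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        basis, projected, evals = gram_project(x)
        np.testing.assert_allclose(sorted(evals, reverse=True), [3.0, 1.0],
                                   atol=1e-12)
        expected = np.column_stack([
            np.array([1.0, 1.0, 2.0]) / np.sqrt(6),
            np.array([1.0, -1.0, 0.0]) / np.sqrt(2),
        ])
        assert_columns_match_up_to_sign(basis, expected, atol=1e-12)
        np.testing.assert_allclose(projected, basis.T @ x, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_gram_eigenvalues_equal_scatter_eigenvalues(self, seed):
        """Nonzero spectra of X'X and XX' coincide (snapshot identity)."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(6, 3))
        _, _, evals = gram_project(x)
        full = np.sort(np.linalg.eigvalsh(x @ x.T))[::-1][:len(evals)]
        np.testing.assert_allclose(evals, full, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_equivalence_with_direct_scatter_decomposition(self, seed):
        """Basis columns match eigenvectors of the m x m scatter up to sign."""
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=(30, 7))
        basis, _, evals = gram_project(x)
        w, v = np.linalg.eigh(x @ x.T)
        order = np.argsort(-w)[:len(evals)]
        assert_columns_match_up_to_sign(basis, v[:, order])

    def test_duplicate_columns_drop_rank(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 4))
        x[:, 3] = x[:, 2]
        basis, projected, evals = gram_project(x)
        assert len(evals) == 3
        assert projected.shape == (3, 4)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero matrix"):
            gram_project(np.zeros((5, 3)))

    def test_orthonormal_basis(self):
        rng = np.random.default_rng(2)
        basis, _, _ = gram_project(rng.normal(size=(20, 5)))
        np.testing.assert_allclose(basis.T @ basis, np.eye(5), atol=1e-8)

    def test_raw_mode_matches_literal_formula(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 4))
        basis, _, evals = gram_project(x, mode="raw")
        # raw columns are X @ eigvec, so their norms are sqrt(eigenvalue)
        np.testing.assert_allclose(np.linalg.norm(basis, axis=0) ** 2, evals,
                                   atol=1e-8)


class TestClassStats:
    def test_hand_computed_two_dim_example(self):
        projected = np.array([[1.0, -1.0, 0.0, 0.0],
                              [0.0, 0.0, 2.0, -2.0]])
        labels = ["control", "control", "case", "case"]
        c_n, c_d, c_b = class_stats(projected, labels)
        np.testing.assert_allclose(c_n, [[1.0, 0.0], [0.0, 0.0]], atol=1e-12)
        np.testing.assert_allclose(c_d, [[0.0, 0.0], [0.0, 4.0]], atol=1e-12)
        np.testing.assert_allclose(c_b, np.zeros((2, 2)), atol=1e-12)

    def test_equal_class_means_zero_between(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(3, 4))
        y = y - y.mean(axis=1, keepdims=True)
        projected = np.concatenate([y + 5, y + 5], axis=1)  # identical means
        c_n, c_d, c_b = class_stats(projected, ["control"] * 4 + ["case"] * 4)
        np.testing.assert_allclose(c_b, 0, atol=1e-12)

    def test_single_sample_class_has_zero_covariance(self):
        projected = np.array([[1.0, 2.0, 7.0], [0.0, 4.0, 1.0]])
        c_n, c_d, _ = class_stats(projected, ["control", "control", "case"])
        np.testing.assert_allclose(c_d, 0, atol=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            class_stats(np.ones((2, 3)), ["control"] * 3)


class TestWeightedCovariance:
    def test_forced_arithmetic_example(self):
        c_n = np.array([[1.0, 0.0], [0.0, 0.0]])
        c_d = np.array([[0.0, 0.0], [0.0, 1.0]])
        c_b = np.array([[1.0, 1.0], [1.0, 1.0]])
        c = weighted_covariance(c_n, c_d, c_b, APCAParams(a=0.3, b=20.0))
        np.testing.assert_allclose(c, [[20.3, 20.0], [20.0, 20.7]], atol=1e-12)

    def test_zero_inputs_give_zero(self):
        z = np.zeros((3, 3))
        np.testing.assert_array_equal(
            weighted_covariance(z, z, z, APCAParams(a=0.5, b=7.0)), z)

    @pytest.mark.parametrize("a", [0.0, 1.0, -0.2, 1.5])
    def test_weight_a_outside_open_interval_rejected(self, a):
        with pytest.raises(ValueError, match="a must"):
            APCAParams(a=a, b=1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_sample_fraction_weights_recover_total_covariance(self, seed):
        """a = n/l, b = 1 reproduces the covariance about the global mean."""
        rng = np.random.default_rng(seed)
        n, d = 6, 4
        projected = rng.normal(size=(5, n + d))
        labels = ["control"] * n + ["case"] * d
        c = weighted_covariance(*class_stats(projected, labels),
                                APCAParams(a=n / (n + d), b=1.0))
        centered = projected - projected.mean(axis=1, keepdims=True)
        total = centered @ centered.T / (n + d)
        np.testing.assert_allclose(c, total, atol=1e-10)


class TestDecompose:
    def test_proportions_from_known_eigenvalues(self):
        res = decompose(np.diag([3.0, 1.0]))
        np.testing.assert_allclose(res.proportions, [0.75, 0.25])
        np.testing.assert_allclose(res.cumulative, [0.75, 1.0])

    def test_identity_ties_keep_index_order(self):
        res = decompose(np.eye(3))
        np.testing.assert_allclose(res.proportions, np.full(3, 1 / 3))
        np.testing.assert_allclose(np.abs(res.eigenvectors), np.eye(3),
                                   atol=1e-12)

    def test_proportions_sum_to_one_and_cumulative_monotone(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(6, 6))
        res = decompose(a @ a.T)
        assert abs(res.proportions.sum() - 1.0) < 1e-9
        assert np.all(np.diff(res.cumulative) >= -1e-12)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            decompose(np.array([[1.0, np.nan], [np.nan, 1.0]]))


class TestGeneScores:
    def test_identity_back_projection(self):
        rng = np.random.default_rng(0)
        basis, _, _ = gram_project(rng.normal(size=(8, 3)))
        vecs = np.eye(3)
        s = gene_scores(basis, vecs, k=1)
        expected = basis[:, 0]
        if expected[np.argmax(np.abs(expected))] < 0:
            expected = -expected
        np.testing.assert_allclose(s, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_unit_norm_under_orthonormal_basis(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(25, 6))
        basis, projected, _ = gram_project(x)
        res = decompose(np.cov(projected, bias=True))
        s = gene_scores(basis, res.eigenvectors, k=2)
        assert abs(np.linalg.norm(s) - 1.0) < 1e-8
        # independent oracle: plain matrix product with the same sign rule
        v = res.eigenvectors[:, 1]
        brute = basis @ v
        if brute[np.argmax(np.abs(brute))] < 0:
            brute = -brute
        np.testing.assert_allclose(s, brute, atol=1e-12)

    def test_sign_rule_max_entry_positive(self):
        rng = np.random.default_rng(5)
        basis, projected, _ = gram_project(rng.normal(size=(30, 5)))
        res = decompose(np.cov(projected, bias=True))
        for k in range(1, 6):
            s = gene_scores(basis, res.eigenvectors, k=k)
            assert s[np.argmax(np.abs(s))] > 0

    def test_k_out_of_range(self):
        basis = np.eye(3)
        with pytest.raises(ValueError, match="out of range"):
            gene_scores(basis, np.eye(3), k=4)


class TestFactorLoadings:
    def test_proportional_column_loads_one(self):
        pc = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.column_stack([2 * pc + 3, -pc])
        fl = factor_loadings(x, pc)
        np.testing.assert_allclose(fl, [1.0, -1.0], atol=1e-12)

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(50, 6))
        pc = rng.normal(size=50)
        fl = factor_loadings(x, pc)
        oracle = [np.corrcoef(x[:, j], pc)[0, 1] for j in range(6)]
        np.testing.assert_allclose(fl, oracle, atol=1e-12)
        assert np.all(np.abs(fl) <= 1 + 1e-12)

    def test_zero_variance_column_errors(self):
        x = np.column_stack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            factor_loadings(x, np.arange(4.0))


class TestFullDecomposition:
    def test_balanced_half_weight_equals_pca_baseline(self, random_labelled):
        """With equal class sizes, a=0.5 and b=1 is exactly standard PCA."""
        x = random_labelled(m=40, n=5, d=5, seed=3)
        sym = apca(x, APCAParams(a=0.5, b=1.0))
        base = pca_baseline(x)
        np.testing.assert_allclose(sym.eigenvalues, base.eigenvalues,
                                   atol=1e-10)

    def test_pca_baseline_matches_covariance_oracle(self, random_labelled):
        """Baseline proportions equal a direct eigendecomposition of the
        sample covariance of the projected coordinates."""
        x = random_labelled(m=200, n=7, d=5, seed=8)
        base = pca_baseline(x)
        _, projected, _ = gram_project(x)
        cov = np.cov(projected, bias=True)
        oracle = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(base.eigenvalues, oracle, atol=1e-8)
        np.testing.assert_allclose(base.proportions, oracle / oracle.sum(),
                                   atol=1e-8)

    def test_permutation_invariance(self, random_labelled):
        x = random_labelled(m=30, n=6, d=4, seed=4)
        dec = apca(x, APCAParams(a=0.3, b=20.0))
        s = gene_scores(dec.basis, dec.eigen.eigenvectors, k=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(x.n_samples)
        xp = ExpressionMatrix(x.values[:, perm],
                              x.probe_ids,
                              [x.sample_ids[j] for j in perm],
                              [x.labels[j] for j in perm])
        dec_p = apca(xp, APCAParams(a=0.3, b=20.0))
        sp = gene_scores(dec_p.basis, dec_p.eigen.eigenvectors, k=2)
        np.testing.assert_allclose(dec_p.eigenvalues, dec.eigenvalues,
                                   atol=1e-8)
        np.testing.assert_allclose(sp, s, atol=1e-8)

    def test_scale_covariance(self, random_labelled):
        x = random_labelled(m=30, n=6, d=4, seed=9)
        c = 3.0
        xc = ExpressionMatrix(c * x.values, x.probe_ids, x.sample_ids, x.labels)
        dec = apca(x, APCAParams(a=0.3, b=20.0))
        dec_c = apca(xc, APCAParams(a=0.3, b=20.0))
        np.testing.assert_allclose(dec_c.eigenvalues, c ** 2 * dec.eigenvalues,
                                   rtol=1e-10,
                                   atol=1e-10 * dec.eigenvalues.max())
        np.testing.assert_allclose(dec_c.proportions, dec.proportions,
                                   atol=1e-10)
        np.testing.assert_allclose(dec_c.factor_loadings, dec.factor_loadings,
                                   atol=1e-8)

    def test_factor_loadings_within_bounds(self, random_labelled):
        dec = apca(random_labelled(seed=12), APCAParams(a=0.3, b=20.0))
        assert np.all(np.abs(dec.factor_loadings) <= 1 + 1e-12)

    def test_score_table_shape(self, random_labelled):
        x = random_labelled(m=20, n=4, d=3, seed=2)
        dec = apca(x, APCAParams())
        st = score_table(gene_scores(dec.basis, dec.eigen.eigenvectors, 2),
                         x.probe_ids)
        assert list(st.columns) == ["probe_id", "gene_symbol", "score"]
        assert len(st) == 20
        assert np.isfinite(st["score"]).all()
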