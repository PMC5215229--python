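"""PCA features, most-similar-spectrum search, thresholding and spike repair."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import apri
from apri import (
    APRIConfig,
    ValidationError,
    correlation_matrix,
    despike_dataset,
    find_mss,
    linear_fit,
    locate_and_replace,
    pairwise_sq_distances,
    pca_features,
    standardize_columns,
    standardize_residual,
    threshold_vector,
)


class TestCorrelationMatrix:
    def test_diagonal_is_one(self, rng):
        R = correlation_matrix(rng.standard_normal((10, 6)))
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)

    def test_perfect_anticorrelation(self, rng):
        col = rng.standard_normal(8)
        X = np.column_stack([col, -2.0 * col, rng.standard_normal(8)])
        R = correlation_matrix(X)
        assert R[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_definition_sums(self):
        # 4x3 integer toy matrix, R computed entry-wise from cov and sigma
        X = np.array([[1, 2, 0], [3, 5, 1], [2, 4, 4], [6, 9, 2]], dtype=float)
        R = correlation_matrix(X)
        m = X.shape[0]
        mu = X.mean(axis=0)
        for j in range(3):
            for l in range(3):
                cov = np.sum((X[:, j] - mu[j]) * (X[:, l] - mu[l])) / m
                sj = np.sqrt(np.sum((X[:, j] - mu[j]) ** 2) / m)
                sl = np.sqrt(np.sum((X[:, l] - mu[l]) ** 2) / m)
                assert R[j, l] == pytest.approx(cov / (sj * sl), abs=1e-12)

    def test_zero_variance_column_zeroed(self, rng, caplog):
        X = rng.standard_normal((6, 4))
        X[:, 2] = 7.0
        with caplog.at_level("WARNING"):
            R = correlation_matrix(X)
        assert np.all(R[2, :] == 0.0) and np.all(R[:, 2] == 0.0)
        assert any("zero-variance" in rec.message for rec in caplog.records)


class TestPCAFeatures:
    def test_proportions_sum_to_one(self, rng):
        model = pca_features(rng.standard_normal((12, 7)))
        assert model.proportions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_rank_one_data_needs_one_component(self, rng):
        pattern = rng.standard_normal(9)
        coef = rng.uniform(1, 2, 15)
        X = np.outer(coef, pattern) + 3.0
        model = pca_features(X, variance_threshold=1.0 - 1e-9)
        assert model.retained_q == 1

    def test_q_is_minimal_index_reaching_threshold(self, rng):
        X = rng.standard_normal((30, 8)) @ np.diag([5, 3, 2, 1, 0.5, 0.3, 0.2, 0.1])
        model = pca_features(X, variance_threshold=0.85)
        cum = np.cumsum(model.proportions)
        q = model.retained_q
        assert cum[q - 1] >= 0.85 - 1e-12
        if q > 1:
            assert cum[q - 2] < 0.85

    def test_eigenvalues_match_characteristic_polynomial(self):
        import sympy

        X = np.array([[2, 1, 0], [1, 3, 1], [0, 1, 4],
                      [2, 0, 1], [3, 2, 2]], dtype=float)
        model = pca_features(X, variance_threshold=1.0)
        R = correlation_matrix(X)
        lam = sympy.symbols("lam")
        charpoly = sympy.Matrix(R).charpoly(lam)
        roots = np.sort(np.array(
            [complex(r).real for r in sympy.nroots(charpoly.as_expr())]
        ))[::-1]
        np.testing.assert_allclose(model.eigenvalues, roots, atol=1e-8)

    def test_orthonormal_eigenvectors(self, rng):
        model = pca_features(rng.standard_normal((20, 10)))
        V = model.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(10), atol=1e-8)

    def test_scores_match_svd_route(self, rng):
        # independent route: SVD of standardized columns
        for _ in range(5):
            m = int(rng.integers(5, 50))
            n = int(rng.integers(3, 30))
            X = rng.standard_normal((m, n)) * rng.uniform(0.5, 10, n)
            model = pca_features(X, variance_threshold=1.0)
            Z = standardize_columns(X)
            U, s, Vt = np.linalg.svd(Z, full_matrices=False)
            k = min(m, n)
            np.testing.assert_allclose(
                model.eigenvalues[:k], s**2 / m, atol=1e-8
            )
            scores_svd = Z @ Vt.T
            for comp in range(min(model.retained_q, k)):
                a = model.scores[:, comp]
                b = scores_svd[:, comp]
                sign = np.sign(np.dot(a, b)) or 1.0
                np.testing.assert_allclose(a, sign * b, atol=1e-6)

    def test_sklearn_cross_check(self, rng):
        from sklearn.decomposition import PCA

        X = rng.standard_normal((25, 8)) * rng.uniform(1, 5, 8)
        model = pca_features(X, variance_threshold=1.0)
        Z = standardize_columns(X)
        skl = PCA(n_components=8).fit(Z)
        np.testing.assert_allclose(
            model.eigenvalues, skl.explained_variance_ * (24 / 25), atol=1e-8
        )


class TestPairwiseSqDistances:
    def test_zero_diagonal_and_345(self):
        D = pairwise_sq_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 0] == 0.0 and D[1, 1] == 0.0
        assert D[0, 1] == pytest.approx(25.0)

    def test_matches_triple_loop(self, rng):
        S = rng.standard_normal((6, 3))
        D = pairwise_sq_distances(S)
        for i in range(6):
            for j in range(6):
                expected = sum((S[i, k] - S[j, k]) ** 2 for k in range(3))
                assert D[i, j] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(D, D.T)


class TestFindMSS:
    def test_two_spectra_forced_choice(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert find_mss(D, 0) == 1
        assert find_mss(D, 1) == 0

    def test_tie_broken_to_smallest_index(self):
        D = np.array([
            [0.0, 5.0, 2.0, 2.0],
            [5.0, 0.0, 1.0, 1.0],
            [2.0, 1.0, 0.0, 3.0],
            [2.0, 1.0, 3.0, 0.0],
        ])
        assert find_mss(D, 0) == 2

    def test_exclusion_gives_second_nearest(self, rng):
        S = rng.standard_normal((8, 3))
        D = pairwise_sq_distances(S)
        for i in range(8):
            order = np.argsort(D[i], kind="stable")
            order = [j for j in order if j != i]
            assert find_mss(D, i) == order[0]
            assert find_mss(D, i, excluded={order[0]}) == order[1]

    def test_all_excluded_raises(self):
        D = np.zeros((2, 2))
        with pytest.raises(ValidationError):
            find_mss(D, 0, excluded={1})


class TestLinearFit:
    def test_identity_fit(self, rng):
        y = rng.standard_normal(30)
        a, b, y_re, S = linear_fit(y, y)
        assert a == pytest.approx(1.0) and b == pytest.approx(0.0, abs=1e-12)
        assert S == pytest.approx(0.0, abs=1e-18)

    def test_exact_affine_relation(self, rng):
        y_star = rng.standard_normal(25)
        a, b, _, S = linear_fit(y_star, 2.0 * y_star + 3.0)
        assert a == pytest.approx(2.0, abs=1e-12)
        assert b == pytest.approx(3.0, abs=1e-12)
        assert S < 1e-20

    def test_matches_normal_equations(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 40))
            y_star = rng.standard_normal(n) * 5
            y = rng.standard_normal(n) * 5
            a, b, _, _ = linear_fit(y_star, y)
            A = np.column_stack([y_star, np.ones(n)])
            sol = np.linalg.solve(A.T @ A, A.T @ y)
            assert a == pytest.approx(sol[0], abs=1e-12)
            assert b == pytest.approx(sol[1], abs=1e-12)

    def test_small_example_normal_equations(self):
        a, b, _, _ = linear_fit(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 2.0]))
        A = np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]])
        sol = np.linalg.solve(A.T @ A, A.T @ np.array([1.0, 2.0, 2.0]))
        assert (a, b) == pytest.approx(tuple(sol), abs=1e-12)

    def test_constant_reference_warns(self):
        with pytest.warns(RuntimeWarning):
            a, b, _, _ = linear_fit(np.full(5, 2.0), np.arange(5.0))
        assert a == 0.0 and b == pytest.approx(2.0)


class TestStandardizeResidual:
    def test_unit_sigma_unchanged(self, rng):
        e = rng.standard_normal(500)
        e = (e - 0) / np.sqrt(((e - e.mean()) ** 2).mean())
        np.testing.assert_allclose(standardize_residual(e), e, rtol=1e-12)

    def test_direct_definition(self):
        e = np.array([0.0, 2.0, 4.0])
        sigma = np.sqrt(8.0 / 3.0)  # population std
        np.testing.assert_allclose(standardize_residual(e), e / sigma, rtol=1e-12)
        assert sigma == pytest.approx(1.6329931618554521)

    def test_constant_residual_returns_zeros(self):
        np.testing.assert_array_equal(standardize_residual(np.full(4, 3.0)),
                                      np.zeros(4))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        e=arrays(np.float64, st.integers(3, 50),
                 elements=st.floats(-1e3, 1e3)),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, e, c):
        sigma = np.sqrt(((e - e.mean()) ** 2).mean())
        if sigma < 1e-9:
            return
        np.testing.assert_allclose(
            standardize_residual(c * e), standardize_residual(e),
            rtol=1e-9, atol=1e-9,
        )


class TestThresholdVector:
    def test_iid_small_residuals_nothing_flagged(self, rng):
        E0 = rng.uniform(-0.5, 0.5, (20, 6))
        t = threshold_vector(E0, -1.0)
        assert np.all(np.isinf(t))

    def test_single_abrupt_drop(self):
        col = np.array([12.0, 0.5, 0.3, 0.1])
        E0 = np.column_stack([col, np.full(4, 0.2)])
        t = threshold_vector(E0, -1.0)
        assert t[0] == 12.0
        assert np.isinf(t[1])
        flagged = E0[:, 0] >= t[0]
        assert list(flagged) == [True, False, False, False]

    def test_all_negative_column_ignored(self):
        E0 = np.column_stack([-np.arange(1.0, 6.0), np.full(5, 0.1)])
        assert np.all(np.isinf(threshold_vector(E0, -1.0)))

    def test_deepest_qualifying_rank_flags_all_spikes(self):
        # two spikes of different size in one channel: threshold at the lower
        col = np.array([20.0, 8.0, 0.4, 0.3, 0.2])
        E0 = np.column_stack([col, np.full(5, 0.1)])
        t = threshold_vector(E0, -1.0)
        assert t[0] == 8.0
        assert (col >= t[0]).sum() == 2

    def test_floor_blocks_subcritical_gap_events(self):
        # a gap of 1.2 between ordinary-magnitude order statistics is noise,
        # not a spike; the outlier floor must reject it
        col = np.array([3.4, 2.2, 1.9, 1.2, 0.4])
        E0 = np.column_stack([col, np.full(5, 0.1)])
        assert np.isinf(threshold_vector(E0, -1.0, residual_floor=5.0)[0])
        assert threshold_vector(E0, -1.0, residual_floor=0.0)[0] == 3.4


class TestLocateAndReplace:
    def test_no_centers_identity(self, rng):
        y = rng.standard_normal(100)
        y_re = rng.standard_normal(100)
        corrected, mask = locate_and_replace(
            y, y_re, np.zeros(100), np.full(100, np.inf), 41)
        assert not mask.any()
        np.testing.assert_array_equal(corrected, y)

    def test_centered_window_coverage(self):
        n = 977
        e = np.zeros(n)
        e[500] = 10.0
        t = np.full(n, 5.0)
        _, mask = locate_and_replace(np.zeros(n), np.zeros(n), e, t, 41)
        assert set(np.flatnonzero(mask)) == set(range(480, 521))

    def test_boundary_clipping(self):
        n = 977
        e = np.zeros(n)
        e[5] = 10.0
        t = np.full(n, 5.0)
        _, mask = locate_and_replace(np.zeros(n), np.zeros(n), e, t, 41)
        assert set(np.flatnonzero(mask)) == set(range(0, 26))

    def test_overlapping_zones_merge(self):
        n = 200
        e = np.zeros(n)
        e[[100, 110]] = 10.0
        t = np.full(n, 5.0)
        _, mask = locate_and_replace(np.zeros(n), np.zeros(n), e, t, 41)
        assert set(np.flatnonzero(mask)) == set(range(80, 131))


class TestDespikeDataset:
    def test_refuses_below_three_spectra(self, rng):
        with pytest.raises(ValidationError):
            despike_dataset(rng.standard_normal((2, 30)))

    def test_spike_free_data_untouched(self, rng):
        base = np.sin(np.linspace(0, 6, 200)) * 50 + 100
        X = base + rng.normal(0, 2, (30, 200)) + rng.uniform(
            0.9, 1.1, 30)[:, None] * 0
        result = despike_dataset(X)
        assert result.spike_mask.mean() < 0.01
        untouched = ~result.spike_mask
        np.testing.assert_array_equal(result.corrected[untouched], X[untouched])

    def test_injected_spike_recovered(self, rng):
        base = 100 + 80 * np.exp(-0.5 * ((np.arange(300) - 150) / 10.0) ** 2)
        sigma = 2.0
        X = base + rng.normal(0, sigma, (20, 300))
        X[7, 111] += 20 * sigma * 10  # large, narrow, positive
        result = despike_dataset(X)
        assert result.spike_mask[7, 111]
        assert abs(result.corrected[7, 111] - base[111]) < 3 * sigma * 3
        # untouched channels are bit-identical
        untouched = ~result.spike_mask
        np.testing.assert_array_equal(result.corrected[untouched], X[untouched])

    def test_mss_never_self(self, rng):
        X = rng.standard_normal((15, 60)) + 10
        result = despike_dataset(X)
        assert np.all(result.mss_index != np.arange(15))

    def test_homogeneous_scale_gives_identity_fit(self, rng):
        base = 100 + 50 * np.sin(np.linspace(0, 10, 150))
        X = base + rng.normal(0, 0.5, (12, 150))
        result = despike_dataset(X)
        np.testing.assert_allclose(result.reg_a, 1.0, atol=0.1)
        np.testing.assert_allclose(result.reg_b, 0.0, atol=np.abs(base).max() * 0.1)

    def test_scale_equivariant_mask(self, rng):
        base = 100 + 80 * np.exp(-0.5 * ((np.arange(200) - 60) / 8.0) ** 2)
        X = base * rng.uniform(0.9, 1.1, (25, 1)) + rng.normal(0, 2, (25, 200))
        X[3, 50] += 500.0
        r1 = despike_dataset(X)
        r2 = despike_dataset(X * 1000.0)
        np.testing.assert_array_equal(r1.spike_mask, r2.spike_mask)
        assert r1.spike_mask[3, 50]

    def test_distances_symmetric_zero_diagonal(self, rng):
        X = rng.standard_normal((10, 40)) + 5
        result = despike_dataset(X)
        D = result.distances
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_array_equal(np.diag(D), 0.0)
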