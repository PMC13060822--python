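import numpy as np
import pytest
from scipy import linalg, optimize

from actibrain.cca import (
    BipartialCCA,
    approximation_test,
    cross_loadings,
    fit_bipartial_cca,
    fit_cca,
    permutation_test,
    variance_explained,
)


def eig_oracle_rho(X, Y):
    """Independent oracle: canonical correlations as sqrt-eigenvalues of
    Sxx^-1 Sxy Syy^-1 Syx via a dense generalized eigendecomposition."""
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    n = X.shape[0]
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    M = linalg.solve(Sxx, Sxy) @ linalg.solve(Syy, Sxy.T)
    w = np.sort(np.real(linalg.eigvals(M)))[::-1]
    k = min(X.shape[1], Y.shape[1])
    return np.sqrt(np.clip(w[:k], 0, 1))


def brute_force_rho1(X, Y, n_starts=4, seed=0):
    """Directly maximize corr(Xw, Yv) over weight vectors."""
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    p, q = X.shape[1], Y.shape[1]

    def neg_corr(wv):
        u = Xc @ wv[:p]
        v = Yc @ wv[p:]
        su, sv = u.std(), v.std()
        if su == 0 or sv == 0:
            return 0.0
        return -np.corrcoef(u, v)[0, 1]

    rng = np.random.default_rng(seed)
    best = 0.0
    for _ in range(n_starts):
        res = optimize.minimize(
            neg_corr, rng.standard_normal(p + q), method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
        )
        res = optimize.minimize(neg_corr, res.x, method="Powell",
                                options={"maxiter": 20000})
        best = max(best, -res.fun)
    return best


class TestFitCCA:
    def test_self_correlation_all_ones(self, rng):
        X = rng.standard_normal((60, 4))
        est = fit_cca(X, X.copy())
        np.testing.assert_allclose(est.rho_, 1.0, atol=1e-8)

    def test_scalar_case_equals_abs_pearson(self, rng):
        x = rng.standard_normal((80, 1))
        y = 0.4 * x + rng.standard_normal((80, 1))
        est = fit_cca(x, y)
        assert est.rho_[0] == pytest.approx(
            abs(np.corrcoef(x.ravel(), y.ravel())[0, 1]), abs=1e-10
        )

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.standard_normal((200, 4))
        Y = 0.3 * X[:, :2] @ rng.standard_normal((2, 6)) + rng.standard_normal((200, 6))
        est = fit_cca(X, Y)
        np.testing.assert_allclose(est.rho_, eig_oracle_rho(X, Y), atol=1e-8)

    def test_primary_mode_matches_direct_maximization(self, rng):
        X = rng.standard_normal((200, 4))
        Y = 0.5 * X[:, :1] + rng.standard_normal((200, 6))
        est = fit_cca(X, Y)
        assert est.rho_[0] == pytest.approx(brute_force_rho1(X, Y), abs=1e-6)

    def test_variates_realize_canonical_correlations(self, rng):
        X = rng.standard_normal((150, 5))
        Y = rng.standard_normal((150, 7)) + 0.5 * X @ rng.standard_normal((5, 7))
        est = fit_cca(X, Y)
        for j in range(5):
            assert np.corrcoef(est.x_scores_[:, j], est.y_scores_[:, j])[
                0, 1
            ] == pytest.approx(est.rho_[j], abs=1e-8)
        # variates unit variance, mutually uncorrelated
        np.testing.assert_allclose(est.x_scores_.std(0, ddof=1), 1.0, atol=1e-8)
        C = np.corrcoef(est.x_scores_, rowvar=False)
        np.testing.assert_allclose(C, np.eye(5), atol=1e-7)

    def test_descending_rho_in_unit_interval(self, rng):
        X = rng.standard_normal((100, 6))
        Y = rng.standard_normal((100, 8))
        est = fit_cca(X, Y)
        assert np.all(np.diff(est.rho_) <= 1e-12)
        assert np.all((est.rho_ >= 0) & (est.rho_ <= 1))

    def test_invariance_under_invertible_mixing(self, rng):
        X = rng.standard_normal((300, 5))
        Y = rng.standard_normal((300, 5)) + 0.4 * X
        A = rng.standard_normal((5, 5)) + 2 * np.eye(5)
        est1 = fit_cca(X, Y)
        est2 = fit_cca(X @ A, Y)
        np.testing.assert_allclose(est1.rho_, est2.rho_, atol=1e-6)

    def test_n_too_small_rejected(self, rng):
        with pytest.raises(ValueError, match="n > max"):
            fit_cca(rng.standard_normal((5, 6)), rng.standard_normal((5, 3)))

    def test_sign_convention_largest_x_loading_positive(self, rng):
        X = rng.standard_normal((200, 4))
        Y = np.hstack(
            [0.6 * X[:, :2] + rng.standard_normal((200, 2)),
             rng.standard_normal((200, 3))]
        )
        est = fit_cca(X, Y)
        for j in range(est.rho_.size):
            load = est.x_loadings_[:, j]
            assert load[np.argmax(np.abs(load))] > 0


class TestBipartialCCA:
    def test_intercept_only_equals_plain_cca(self, rng):
        X = rng.standard_normal((120, 3))
        Y = rng.standard_normal((120, 4)) + 0.3 * X @ rng.standard_normal((3, 4))
        plain = BipartialCCA(scale=True).fit(X, Y)
        withones = BipartialCCA(scale=True).fit(
            X, Y, confounders_x=np.ones((120, 1)), confounders_y=np.ones((120, 1))
        )
        np.testing.assert_allclose(plain.rho_, withones.rho_, atol=1e-10)

    def test_confounder_only_association_removed(self, rng):
        """Association driven purely by a shared confounder vanishes after
        residualization: rho_1 falls to the null scale."""
        g = rng.standard_normal((500, 1))
        X = 0.9 * g + rng.standard_normal((500, 3)) * 0.5
        Y = 0.9 * g + rng.standard_normal((500, 4)) * 0.5
        naive = BipartialCCA().fit(X, Y)
        adjusted = BipartialCCA().fit(X, Y, confounders_x=g, confounders_y=g)
        assert naive.rho_[0] > 0.5
        null_scale = 3 * np.sqrt((3 + 4) / 500)
        assert adjusted.rho_[0] < null_scale

    def test_variates_uncorrelated_with_confounders(self, small_cohort):
        coh = small_cohort
        Gx = coh.confounders["pa"].to_numpy()
        Gy = coh.confounders["fc"].to_numpy()
        est = BipartialCCA().fit(
            coh.pa.to_numpy(), coh.fc_edges.to_numpy(),
            confounders_x=Gx, confounders_y=Gy,
        )
        for j in range(3):
            for c in range(Gx.shape[1]):
                assert abs(np.corrcoef(est.x_scores_[:, j], Gx[:, c])[0, 1]) < 1e-8
                assert abs(np.corrcoef(est.y_scores_[:, j], Gy[:, c])[0, 1]) < 1e-8

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="row mismatch"):
            BipartialCCA().fit(
                rng.standard_normal((50, 3)), rng.standard_normal((40, 3))
            )


class TestApproximationTest:
    def test_all_zero_rho(self):
        rep = approximation_test(np.zeros(3), n=100, p=3, q=5)
        np.testing.assert_allclose(rep.statistic, 0.0, atol=1e-12)
        np.testing.assert_allclose(rep.p_values, 1.0)

    def test_statistic_matches_log_sum_oracle(self, rng):
        rho = np.sort(rng.uniform(0.05, 0.6, 4))[::-1]
        n, p, q = 300, 4, 7
        rep = approximation_test(rho, n, p, q)
        c = n - 1 - (p + q + 1) / 2
        for s in range(1, 5):
            lam = np.prod([1 - r**2 for r in rho[s - 1 :]])
            assert rep.statistic[s - 1] == pytest.approx(-c * np.log(lam), abs=1e-10)
            assert rep.df[s - 1] == (p - s + 1) * (q - s + 1)

    def test_strong_signal_significant_null_not(self, rng):
        z = rng.standard_normal(400)
        X = np.column_stack([z + 0.5 * rng.standard_normal(400),
                             rng.standard_normal((400, 2))])
        Y = np.column_stack([z + 0.5 * rng.standard_normal(400),
                             rng.standard_normal((400, 3))])
        est = fit_cca(X, Y)
        rep = est.approximation_test()
        assert rep.p_values[0] < 1e-6
        assert rep.p_values[1] > 0.01

    def test_rao_f_close_to_bartlett(self, rng):
        rho = np.array([0.4, 0.15, 0.05])
        a = approximation_test(rho, 500, 3, 6, method="bartlett")
        b = approximation_test(rho, 500, 3, 6, method="rao")
        np.testing.assert_allclose(a.p_values, b.p_values, atol=0.01)

    def test_degenerate_rho_rejected(self):
        with pytest.raises(ValueError):
            approximation_test(np.array([1.0]), 100, 2, 2)


class TestPermutationTest:
    def test_planted_signal_attains_minimum_p(self, rng):
        z = rng.standard_normal(1000)
        X = np.column_stack([z, rng.standard_normal((1000, 3))]) + \
            0.8 * rng.standard_normal((1000, 4))
        Y = np.column_stack([z, rng.standard_normal((1000, 5))]) + \
            0.8 * rng.standard_normal((1000, 6))
        rep = permutation_test(X - X.mean(0), Y - Y.mean(0),
                               n_permutations=199, seed=5)
        assert rep.p_values[0] == pytest.approx(1 / 200)

    def test_seeded_reproducibility(self, rng):
        X = rng.standard_normal((100, 3))
        Y = rng.standard_normal((100, 4))
        r1 = permutation_test(X, Y, 99, seed=11)
        r2 = permutation_test(X, Y, 99, seed=11)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)

    def test_minimum_permutation_count_enforced(self, rng):
        with pytest.raises(ValueError):
            permutation_test(
                rng.standard_normal((50, 2)), rng.standard_normal((50, 2)), 50
            )

    def test_p_values_bounded_below(self, rng):
        X = rng.standard_normal((80, 2))
        Y = rng.standard_normal((80, 3))
        rep = permutation_test(X, Y, 99, seed=0)
        assert np.all(rep.p_values >= 1 / 100)


class TestVarianceExplained:
    def test_single_column_block(self, rng):
        y = rng.standard_normal((100, 1))
        v = 0.7 * y.ravel() + rng.standard_normal(100)
        v = (v - v.mean()) / v.std(ddof=1)
        ve = variance_explained(y, v)
        assert ve[0] == pytest.approx(np.corrcoef(y.ravel(), v)[0, 1] ** 2)

    def test_full_mode_set_sums_to_one(self, rng):
        X = rng.standard_normal((120, 5))
        Y = rng.standard_normal((120, 8))
        est = fit_cca(X, Y)
        assert est.variance_explained("x").sum() == pytest.approx(1.0, abs=1e-8)

    def test_matches_per_column_regression_oracle(self, rng):
        B = rng.standard_normal((20, 5)) * rng.uniform(0.5, 2.0, 5)
        v = rng.standard_normal(20)
        v = (v - v.mean()) / v.std(ddof=1)
        ve = variance_explained(B, v)
        # oracle: per-column simple-regression R^2, variance weighted
        num = 0.0
        den = 0.0
        for j in range(5):
            r2 = np.corrcoef(B[:, j], v)[0, 1] ** 2
            num += r2 * B[:, j].var(ddof=1)
            den += B[:, j].var(ddof=1)
        assert ve[0] == pytest.approx(num / den, abs=1e-10)

    def test_non_orthogonal_variates_rejected(self, rng):
        B = rng.standard_normal((50, 3))
        v = rng.standard_normal(50)
        V = np.column_stack([v, v + 0.01 * rng.standard_normal(50)])
        with pytest.raises(ValueError, match="uncorrelated"):
            variance_explained(B, V)


class TestCrossLoadings:
    def test_variate_equal_to_column(self, rng):
        B = rng.standard_normal((60, 3))
        out = cross_loadings(B, B[:, 1])
        assert out[1] == pytest.approx(1.0)

    def test_matches_direct_correlation(self, rng):
        B = rng.standard_normal((60, 4))
        v = rng.standard_normal(60)
        out = cross_loadings(B, v)
        for j in range(4):
            assert out[j] == pytest.approx(np.corrcoef(B[:, j], v)[0, 1], abs=1e-12)


class TestPlantedRecovery:
    def test_planted_rho_recovered_on_cohort(self, small_cohort):
        coh = small_cohort
        est = fit_bipartial_cca(
            coh.pa.to_numpy(), coh.fc_edges.to_numpy(),
            coh.confounders["pa"].to_numpy(), coh.confounders["fc"].to_numpy(),
        )
        # n=600 with q=66: sampling noise and overfitting inflate rho_1,
        # but it must sit near the planted 0.50 ground truth
        rho_true = coh.ground_truth["rho_fc"][0]
        assert abs(est.rho_[0] - rho_true) < 0.15
        assert est.approximation_test().p_values[0] < 0.01
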