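import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from actibrain.mass_univariate import (
    MassUnivariateScreen,
    consensus_ranking,
    cv_predictive_correlation,
    importance_random_forest,
    importance_stepwise_bic,
    importance_ttest,
    screen_responses,
)


def brute_force_bh(pvals, alpha):
    """Step-up definition applied literally."""
    p = np.asarray(pvals)
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    k = 0
    for i in range(m):
        if sorted_p[i] <= (i + 1) / m * alpha:
            k = i + 1
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestScreenResponses:
    def test_bh_worked_example(self):
        """p = (0.001, 0.013, 0.9) at alpha 0.05: first two selected."""
        assert brute_force_bh([0.001, 0.013, 0.9], 0.05).tolist() == [
            True, True, False,
        ]

    def test_bh_matches_brute_force_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(300):
            m = rng.integers(1, 15)
            p = rng.random(m)
            reject, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_array_equal(reject, brute_force_bh(p, 0.05))

    def test_partial_f_matches_statsmodels(self, rng):
        n = 120
        G = rng.standard_normal((n, 2))
        H = rng.standard_normal((n, 3))
        Y = (G @ rng.standard_normal((2, 4))
             + H @ rng.standard_normal((3, 4)) * 0.3
             + rng.standard_normal((n, 4)))
        res = screen_responses(Y, G, H)
        G1 = sm.add_constant(G)
        X1 = np.hstack([G1, H])
        for l in range(4):
            full = sm.OLS(Y[:, l], X1).fit()
            red = sm.OLS(Y[:, l], G1).fit()
            f, p, _ = full.compare_f_test(red)
            assert res.f_statistics[l] == pytest.approx(f, abs=1e-10)
            assert res.p_values[l] == pytest.approx(p, abs=1e-10)

    def test_overall_f_matches_statsmodels(self, rng):
        n = 90
        G = rng.standard_normal((n, 2))
        H = rng.standard_normal((n, 3))
        Y = H @ rng.standard_normal((3, 2)) * 0.4 + rng.standard_normal((n, 2))
        res = screen_responses(Y, G, H, test="overall")
        X1 = np.hstack([sm.add_constant(G), H])
        for l in range(2):
            fit = sm.OLS(Y[:, l], X1).fit()
            assert res.f_statistics[l] == pytest.approx(fit.fvalue, abs=1e-10)
            assert res.p_values[l] == pytest.approx(fit.f_pvalue, abs=1e-10)

    def test_exact_linear_response_hits_floor(self, rng):
        n = 80
        G = rng.standard_normal((n, 2))
        H = rng.standard_normal((n, 3))
        Y = np.column_stack([H @ np.array([1.0, -2.0, 0.5]),
                             rng.standard_normal(n)])
        res = screen_responses(Y, G, H)
        assert res.p_values[0] == 0.0
        assert 0 in res.selected

    def test_null_p_values_approximately_uniform(self, rng):
        """With no PA effect, raw p-values are uniform and BH keeps the
        selection rate near the FDR level."""
        from scipy import stats

        n, q = 200, 60
        pvals = []
        n_selected = 0
        for _ in range(25):
            G = rng.standard_normal((n, 2))
            H = rng.standard_normal((n, 3))
            Y = G @ rng.standard_normal((2, q)) + rng.standard_normal((n, q))
            res = screen_responses(Y, G, H)
            pvals.append(res.p_values)
            n_selected += res.selected.size
        ks = stats.kstest(np.concatenate(pvals), "uniform")
        assert ks.pvalue > 0.01
        assert n_selected / (25 * q) < 0.02  # all nulls: few false selections

    def test_rank_deficiency_reported(self, rng):
        G = rng.standard_normal((50, 2))
        H = np.hstack([G[:, :1], rng.standard_normal((50, 2))])
        with pytest.raises(ValueError, match="rank deficient"):
            screen_responses(rng.standard_normal((50, 2)), G, H)


class TestCVPredictiveCorrelation:
    def test_noiseless_linear_response_near_one(self, rng):
        X = rng.standard_normal((200, 3))
        y = X @ np.array([1.0, -1.0, 0.5])
        mean_corr, _ = cv_predictive_correlation(y, X, n_reps=3, seed=0)
        assert mean_corr > 0.999

    def test_pure_noise_near_zero(self, rng):
        X = rng.standard_normal((1000, 3))
        y = rng.standard_normal(1000)
        mean_corr, _ = cv_predictive_correlation(y, X, n_reps=5, seed=0)
        assert abs(mean_corr) < 0.05

    def test_seeded_reproducibility(self, rng):
        X = rng.standard_normal((100, 2))
        y = X[:, 0] + rng.standard_normal(100)
        a = cv_predictive_correlation(y, X, n_reps=4, seed=3)
        b = cv_predictive_correlation(y, X, n_reps=4, seed=3)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])


def _planted_design(rng, n=800, beta=1.0, active=(0, 8)):
    """Signal only in PA columns `active` (TLAC-like and M10-like)."""
    G = rng.standard_normal((n, 2))
    H = rng.standard_normal((n, 11))
    coef = np.zeros(11)
    for a in active:
        coef[a] = beta
    Y = (G @ rng.standard_normal((2, 3)) * 0.5
         + np.outer(H @ coef, np.ones(3))
         + rng.standard_normal((n, 3)))
    return G, H, Y


class TestImportanceTTest:
    def test_matches_statsmodels_pvalues(self, rng):
        G, H, Y = _planted_design(rng, n=150, beta=0.3)
        tab = importance_ttest(Y, G, H)
        X1 = np.hstack([sm.add_constant(G), H])
        fit = sm.OLS(Y[:, 0], X1).fit()
        np.testing.assert_allclose(
            tab.scores.iloc[0].to_numpy(),
            -np.log10(fit.pvalues[3:]),
            atol=1e-8,
        )

    def test_planted_variable_attains_max_score(self, rng):
        G, H, Y = _planted_design(rng, active=(4,))
        tab = importance_ttest(Y, G, H)
        assert tab.scores.mean(axis=0).idxmax() == "PA5"

    def test_duplicate_pa_column_rejected(self, rng):
        G = rng.standard_normal((60, 2))
        H = rng.standard_normal((60, 3))
        H = np.hstack([H, H[:, :1]])
        with pytest.raises(ValueError, match="rank deficient"):
            importance_ttest(rng.standard_normal((60, 2)), G, H)


class TestImportanceStepwiseBIC:
    def test_single_strong_predictor_selected(self, rng):
        G, H, Y = _planted_design(rng, n=2000, beta=0.8, active=(2,))
        tab = importance_stepwise_bic(Y, G, H)
        sel = tab.scores.to_numpy()
        assert np.all(sel[:, 2] == 1)
        assert sel.sum() <= 3 + 2  # little beyond the true variable

    def test_null_design_mostly_empty_selection(self, rng):
        """BIC is consistent: with no PA effect the selected set is empty
        in the large majority of replicates."""
        empty = 0
        for _ in range(20):
            G = rng.standard_normal((1500, 2))
            H = rng.standard_normal((1500, 5))
            Y = rng.standard_normal((1500, 1))
            tab = importance_stepwise_bic(Y, G, H)
            empty += int(tab.scores.to_numpy().sum() == 0)
        assert empty >= 18

    def test_deterministic(self, rng):
        G, H, Y = _planted_design(rng, n=300)
        a = importance_stepwise_bic(Y, G, H).scores
        b = importance_stepwise_bic(Y, G, H).scores
        assert a.equals(b)

    def test_entries_binary(self, rng):
        G, H, Y = _planted_design(rng, n=300)
        vals = importance_stepwise_bic(Y, G, H).scores.to_numpy()
        assert set(np.unique(vals)) <= {0, 1}


class TestImportanceRandomForest:
    def test_planted_nonlinear_effect_detected(self, rng):
        n = 600
        G = rng.standard_normal((n, 2))
        H = rng.standard_normal((n, 6))
        y = H[:, 3] ** 2 + 0.3 * rng.standard_normal(n)
        tab = importance_random_forest(y, G, H, seed=0)
        scores = tab.scores.iloc[0]
        assert scores.idxmax() == "PA4"

    def test_seeded_reproducibility(self, rng):
        G = rng.standard_normal((150, 2))
        H = rng.standard_normal((150, 4))
        y = H[:, 0] + rng.standard_normal(150)
        a = importance_random_forest(y, G, H, seed=7).scores
        b = importance_random_forest(y, G, H, seed=7).scores
        assert a.equals(b)

    def test_minimum_trees_enforced(self, rng):
        with pytest.raises(ValueError):
            importance_random_forest(
                rng.standard_normal(50), rng.standard_normal((50, 1)),
                rng.standard_normal((50, 2)), n_trees=10,
            )


class TestConsensusRanking:
    def _table(self, scores, method):
        return type(
            "T", (), {"scores": pd.DataFrame([scores], columns=["a", "b", "c"]),
                      "method": method},
        )()

    def test_identical_tables_preserve_ranking(self):
        t1 = self._table([3.0, 2.0, 1.0], "ttest")
        t2 = self._table([30.0, 20.0, 10.0], "random_forest")
        out = consensus_ranking([t1, t2])
        assert list(out.index) == ["a", "b", "c"]
        assert out["mean_rank"].tolist() == [1.0, 2.0, 3.0]

    def test_reversed_method_gives_mid_ranks(self):
        t1 = self._table([3.0, 2.0, 1.0], "ttest")
        t2 = self._table([1.0, 2.0, 3.0], "stepwise_bic")
        out = consensus_ranking([t1, t2])
        assert np.allclose(out["mean_rank"].to_numpy(), 2.0)

    def test_mismatched_columns_rejected(self):
        t1 = self._table([1, 2, 3], "ttest")
        t2 = self._table([1, 2, 3], "rf")
        t2.scores.columns = ["x", "y", "z"]
        with pytest.raises(ValueError, match="mismatch"):
            consensus_ranking([t1, t2])


class TestMassUnivariateScreen:
    def test_estimator_workflow(self, rng):
        G, H, Y = _planted_design(rng, n=400, beta=0.5)
        est = MassUnivariateScreen(n_reps=3, seed=1).fit(
            Y, confounders=G, pa=H
        )
        assert est.selected_.size == 3  # every response carries signal
        cv = est.cv_correlations()
        assert np.all(cv > 0.3)
        tab = est.importance("ttest")
        assert tab.scores.shape == (3, 11)
        params = est.get_params()
        assert params["alpha"] == 0.05 and params["n_reps"] == 3
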