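"""Multinomial logit: likelihood identities, oracle agreement, inference,
diagnostics and the IIA specification test."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from paregions.mlr import (
    IIATestResult,
    MLRFit,
    RankDeficiencyError,
    build_design,
    classification_accuracy,
    collinearity_screen,
    design_from_labels,
    fit_mlr,
    hausman_mcfadden_iia,
    hausman_quadratic,
    likelihood_ratio_test,
    max_chance_criterion,
    mlr_analysis,
    pseudo_r2,
    simulate_mlr_data,
    wald_inference,
)


@pytest.fixture(scope="module")
def three_cat_fit():
    rng = np.random.default_rng(10)
    beta = np.array([[0.2, 0.8, -0.5], [-0.3, -0.6, 0.9]])
    X, y = simulate_mlr_data(beta, 600, rng)
    return fit_mlr(design_from_labels(X, y, baseline="2")), X, y, beta


class TestFit:
    def test_intercept_only_recovers_frequencies(self):
        rng = np.random.default_rng(0)
        y = rng.choice(3, size=300, p=[0.5, 0.3, 0.2])
        fit = fit_mlr(design_from_labels(np.empty((300, 0)), y, baseline="2"))
        probs = fit.predict_proba()[0]
        freqs = np.bincount(fit.design.y, minlength=3) / 300
        np.testing.assert_allclose(probs, freqs, atol=1e-8)

    def test_binary_case_matches_logit_oracle(self):
        rng = np.random.default_rng(1)
        X, y = simulate_mlr_data(np.array([[0.5, 1.2, -0.7]]), 400, rng)
        fit = fit_mlr(design_from_labels(X, y, baseline="1"))
        oracle = sm.Logit(1 - y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients[0], oracle.params, atol=1e-6)
        se = np.sqrt(np.diag(fit.covariance))
        np.testing.assert_allclose(se, oracle.bse, atol=1e-6)

    def test_three_categories_match_mnlogit_oracle(self, three_cat_fit):
        fit, X, y, _ = three_cat_fit
        recode = {2: 0, 0: 1, 1: 2}  # statsmodels baselines on category 0
        oracle = sm.MNLogit(np.vectorize(recode.get)(y), sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients.T, oracle.params, atol=1e-6)
        np.testing.assert_allclose(fit.log_likelihood, oracle.llf, atol=1e-8)

    def test_parameter_recovery_within_three_se(self):
        """Simulated-truth recovery: >=95% of coefficients within 3 SE over
        100 seeds at n=5000."""
        beta = np.array([[0.4, 0.6, -0.8], [-0.2, 0.5, 0.3]])
        total = within = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            X, y = simulate_mlr_data(beta, 5000, rng)
            fit = fit_mlr(design_from_labels(X, y, baseline="2"))
            se = np.sqrt(np.diag(fit.covariance)).reshape(2, -1)
            ok = np.abs(fit.coefficients - beta) <= 3 * se
            total += ok.size
            within += ok.sum()
        assert within / total >= 0.95

    def test_rank_deficiency_names_collinear_set(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=200)
        X = np.column_stack([x1, 2 * x1, rng.normal(size=200)])
        y = rng.choice(2, size=200)
        with pytest.raises(RankDeficiencyError, match="x1"):
            fit_mlr(design_from_labels(X, y, baseline="1"))

    def test_separation_is_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = (x > 0.5).astype(int)
        fit = fit_mlr(design_from_labels(x[:, None], y, baseline="1"))
        assert fit.separated or not fit.converged  # flagged, not silent


class TestLikelihoodIdentities:
    def test_probabilities_sum_to_one(self, three_cat_fit):
        fit, *_ = three_cat_fit
        probs = fit.predict_proba()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs > 0).all()

    def test_log_odds_equal_linear_predictor(self, three_cat_fit):
        fit, *_ = three_cat_fit
        probs = fit.predict_proba()
        eta = fit.design.X @ fit.coefficients.T
        log_odds = np.log(probs[:, :-1] / probs[:, [-1]])
        np.testing.assert_allclose(log_odds, eta, atol=1e-9)

    def test_location_shift_moves_only_intercept(self, three_cat_fit):
        fit, X, y, _ = three_cat_fit
        shifted = X.copy()
        shifted[:, 0] += 5.0
        fit2 = fit_mlr(design_from_labels(shifted, y, baseline="2"))
        np.testing.assert_allclose(
            fit2.coefficients[:, 1:], fit.coefficients[:, 1:], atol=1e-6
        )
        np.testing.assert_allclose(
            fit2.coefficients[:, 0],
            fit.coefficients[:, 0] - 5.0 * fit.coefficients[:, 1],
            atol=1e-6,
        )


class TestWaldInference:
    def test_table_is_consistent_with_fit(self, three_cat_fit):
        fit, *_ = three_cat_fit
        table = wald_inference(fit)
        assert len(table) == 2 * 3  # 2 contrasts x (intercept + 2 predictors)
        np.testing.assert_allclose(table["odds_ratio"], np.exp(table["b"]))
        from scipy import stats

        z_crit = stats.norm.ppf(0.975)
        np.testing.assert_allclose(
            table["ci_lower"], np.exp(table["b"] - z_crit * table["se"]), rtol=1e-9
        )
        assert ((table["ci_lower"] <= table["odds_ratio"])
                & (table["odds_ratio"] <= table["ci_upper"])).all()

    def test_zero_coefficient_gives_unit_odds_symmetric_ci(self):
        design = design_from_labels(np.zeros((10, 1)) + np.arange(10)[:, None],
                                    [0, 1] * 5, baseline="1")
        fit = MLRFit(design=design, coefficients=np.array([[0.0, 0.0]]),
                     covariance=np.diag([0.04, 0.04]), log_likelihood=-5.0,
                     null_log_likelihood=-5.0, converged=True, iterations=1,
                     max_score=0.0)
        table = wald_inference(fit)
        assert (table["odds_ratio"] == 1.0).all()
        np.testing.assert_allclose(
            np.log(table["ci_upper"]), -np.log(table["ci_lower"]), atol=1e-12
        )

    def test_significance_stars(self, three_cat_fit):
        fit, *_ = three_cat_fit
        table = wald_inference(fit)
        for _, row in table.iterrows():
            expected = ("***" if row.p_value < 0.01 else
                        "**" if row.p_value < 0.05 else
                        "*" if row.p_value < 0.10 else "")
            assert row.stars == expected


class TestModelFitStatistics:
    def test_lr_test_nesting(self, three_cat_fit):
        fit, X, y, _ = three_cat_fit
        chi2, df, p = likelihood_ratio_test(fit)
        assert df == 2 * 2  # (J-1) * p
        assert chi2 > 0 and p < 0.05
        rng = np.random.default_rng(4)
        X_noise = np.column_stack([X, rng.standard_normal(len(X))])
        fit2 = fit_mlr(design_from_labels(X_noise, y, baseline="2"))
        chi2b, dfb, _ = likelihood_ratio_test(fit2)
        assert dfb == df + 2  # one predictor x (J-1) contrasts
        assert chi2b >= chi2 - 1e-6

    def test_lr_df_for_four_categories_twelve_predictors(self, default_run):
        analysis = mlr_analysis(default_run["covariates"], default_run["solution"])
        assert analysis.diagnostics.lr_df == 36  # 3 contrasts x 12 predictors

    def test_pseudo_r2_formulas(self):
        def fake_fit(n, lln, llf):
            design = design_from_labels(np.empty((n, 0)), np.zeros(n, dtype=int),
                                        baseline="0")
            return MLRFit(design=design, coefficients=np.zeros((0, 1)),
                          covariance=np.zeros((0, 0)), log_likelihood=llf,
                          null_log_likelihood=lln, converged=True, iterations=1,
                          max_score=0.0)

        cs, nk = pseudo_r2(fake_fit(100, -120.0, -120.0))
        assert cs == 0.0 and nk == 0.0
        cs, nk = pseudo_r2(fake_fit(100, -120.0, -80.0))
        assert cs == pytest.approx(1 - np.exp(-0.8))
        assert nk == pytest.approx((1 - np.exp(-0.8)) / (1 - np.exp(-2.4)))

    def test_nagelkerke_dominates_cox_snell(self, three_cat_fit):
        fit, *_ = three_cat_fit
        cs, nk = pseudo_r2(fit)
        assert 0 <= cs <= nk <= 1


class TestClassificationAccuracy:
    def test_reported_arithmetic(self):
        assert max_chance_criterion([73, 31, 57, 35]) == pytest.approx(
            1.25 * 73 / 196)

    def test_equal_categories(self):
        assert max_chance_criterion([25, 25, 25, 25]) == pytest.approx(0.3125)

    def test_separable_data_hits_everything(self):
        x = np.r_[np.zeros(30), 10 * np.ones(30), 20 * np.ones(30)]
        y = np.repeat([0, 1, 2], 30)
        fit = fit_mlr(design_from_labels(x[:, None], y, baseline="2"))
        hit, mc, practical = classification_accuracy(fit)
        assert hit == 1.0
        assert mc == pytest.approx(1.25 / 3)
        assert practical


class TestCollinearity:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        X = np.column_stack([
            np.tile([1.0, -1.0], n // 2),
            np.repeat([1.0, -1.0], n // 2),
            np.tile([1.0, 1.0, -1.0, -1.0], n // 4),
        ])
        table = collinearity_screen(X)
        np.testing.assert_allclose(table["vif"], 1.0, atol=1e-9)
        np.testing.assert_allclose(table["tolerance"], 1.0, atol=1e-9)

    def test_near_collinear_flagged(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=100)
        X = np.column_stack([x1, 2 * x1 + 1e-14 * rng.normal(size=100),
                             rng.normal(size=100)])
        table = collinearity_screen(X)
        assert table["perfectly_collinear"].iloc[0]
        assert np.isinf(table["vif"].iloc[0])

    def test_matches_auxiliary_regression_oracle(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=(300, 3))
        X = z @ np.linalg.cholesky(np.array([[1, 0.5, 0.5],
                                             [0.5, 1, 0.5],
                                             [0.5, 0.5, 1]])).T
        table = collinearity_screen(X)
        for a in range(3):
            others = sm.add_constant(np.delete(X, a, axis=1))
            r2 = sm.OLS(X[:, a], others).fit().rsquared
            assert table["vif"].iloc[a] == pytest.approx(1 / (1 - r2), rel=1e-9)
            assert table["tolerance"].iloc[a] == pytest.approx(1 - r2, rel=1e-9)


class TestHausmanMcFadden:
    def test_identical_estimates_give_zero_statistic(self):
        M = np.diag([0.5, 1.0, 2.0])
        H, df, p, valid, _ = hausman_quadratic(np.zeros(3), M)
        assert H == 0.0 and p == 1.0 and valid and df == 3

    def test_non_pd_difference_is_inconclusive(self):
        M = np.diag([1.0, -0.2, 0.5])
        d = np.array([0.1, 0.3, -0.2])
        H, df, p, valid, note = hausman_quadratic(d, M)
        assert not valid
        assert df == 2  # rank of the non-negative eigenspace
        assert 0 <= p <= 1
        assert "not positive definite" in note

    def test_iia_on_true_multinomial_logit(self):
        rng = np.random.default_rng(7)
        beta = np.array([[0.2, 0.5, -0.4], [-0.1, -0.3, 0.6]])
        X, y = simulate_mlr_data(beta, 2000, rng)
        fit = fit_mlr(design_from_labels(X, y, baseline="2"))
        res = hausman_mcfadden_iia(fit, "0")
        assert isinstance(res, IIATestResult)
        assert res.statistic >= 0 and 0 <= res.p_value <= 1
        assert res.df > 0

    def test_cannot_omit_baseline(self, three_cat_fit):
        fit, *_ = three_cat_fit
        with pytest.raises(ValueError, match="baseline"):
            hausman_mcfadden_iia(fit, "2")

    def test_small_sample_inconclusive_path_no_crash(self):
        # small n makes a non-PD covariance difference very likely; the run
        # must come back flagged rather than crash
        flagged = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            beta = np.array([[0.2, 0.5, -0.4], [-0.1, -0.3, 0.6]])
            X, y = simulate_mlr_data(beta, 120, rng)
            if len(np.unique(y)) < 3:
                continue
            fit = fit_mlr(design_from_labels(X, y, baseline="2"))
            res = hausman_mcfadden_iia(fit, "0")
            flagged += not res.valid
        assert flagged >= 1


class TestFullAnalysis:
    def test_design_reference_coding(self, default_run):
        design = build_design(default_run["covariates"], default_run["solution"])
        assert "agriculture" not in design.predictor_names
        assert "pop_gt64" not in design.predictor_names
        assert len(design.predictor_names) == 12
        assert design.categories[-1] == "unhealthy"

    def test_full_battery_on_default_run(self, default_run):
        analysis = mlr_analysis(default_run["covariates"], default_run["solution"])
        d = analysis.diagnostics
        assert 0 <= d.hit_ratio <= 1
        assert d.nagelkerke_r2 >= d.cox_snell_r2 >= 0
        assert np.allclose(d.collinearity["tolerance"] * d.collinearity["vif"], 1.0)
        assert len(d.iia_tests) == 3  # one per non-baseline category
        assert len(analysis.wald_table) == 3 * 13
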