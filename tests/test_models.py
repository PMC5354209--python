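"""Estimator correctness against closed forms and independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

from costlines import (DesignMatrix, ErrorSpec, GeneratorConfig,
                       GLMCostModel, LogOLSCostModel, build_design,
                       fit_glm_log, fit_log_ols, fit_variance_model,
                       generate_cohort, huber_white_vcov, predict_mean)
from costlines.exceptions import ConvergenceError
from costlines.models import (FittedModel, fit_variance_model_arrays,
                              glm_sandwich_vcov, ols_sandwich_vcov)


def _design(df: pd.DataFrame) -> DesignMatrix:
    X = df.copy()
    X.insert(0, "const", 1.0)
    return DesignMatrix(X=X, column_names=tuple(X.columns))


def _intercept_only(n: int) -> DesignMatrix:
    return _design(pd.DataFrame(index=range(n)))


class TestGLM:
    @pytest.mark.parametrize("family", ["gaussian", "poisson", "gamma",
                                        "inverse_gaussian"])
    def test_intercept_only_reproduces_sample_mean(self, family):
        rng = np.random.default_rng(0)
        y = rng.lognormal(4.0, 1.0, size=500)
        m = fit_glm_log(_intercept_only(len(y)), y, family=family)
        assert np.exp(m.alpha) == pytest.approx(y.mean(), rel=1e-8)

    def test_nonpositive_costs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_glm_log(_intercept_only(4), np.array([1.0, 2.0, 0.0, 3.0]))

    def test_matches_brute_force_gamma_likelihood_maximum(self):
        # independent oracle: direct Nelder-Mead maximization of the gamma
        # quasi-log-likelihood sum(-y/mu - log mu) with mu = exp(a + b x)
        rng = np.random.default_rng(42)
        x = rng.normal(size=20)
        mu = np.exp(1.0 + 0.5 * x)
        y = rng.gamma(2.0, mu / 2.0)
        design = _design(pd.DataFrame({"x": x}))

        def nll(p):
            m = np.exp(p[0] + p[1] * x)
            return np.sum(y / m + np.log(m))

        brute = minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12,
                                  "maxiter": 5000})
        fitted = fit_glm_log(design, y, family="gamma")
        assert fitted.alpha == pytest.approx(brute.x[0], abs=1e-4)
        assert fitted.beta[0] == pytest.approx(brute.x[1], abs=1e-4)

    def test_parameter_recovery_for_large_effects(self):
        true = {"1-0": 1.0, "3-1": 2.0, "5-1": 5.0, "6-2": 20.0,
                "7-3": 100.0}
        cfg = GeneratorConfig(
            category_probs={c: 0.2 for c in true},
            use_prob={"total": 1.0},
            base_cost={"total": 150.0},
            effect=true,
            error_family={"total": ErrorSpec("gamma", shape=2.0)},
            seed=77,
        ).validate()
        cohort = generate_cohort(cfg, 50_000)
        design, y = build_design(cohort, "total")
        m = fit_glm_log(design, y, family="gamma")
        coef = dict(zip(m.column_names, m.params))
        for cat, eff in true.items():
            if cat == "1-0":
                continue
            est = np.exp(coef[f"acrg3_{cat}"])
            assert abs(est - eff) / eff < 0.10, cat

    def test_rescaling_y_only_shifts_intercept(self, gamma_cohort):
        design, y = build_design(gamma_cohort, "total")
        m1 = fit_glm_log(design, y, family="gamma")
        m2 = fit_glm_log(design, y * 7.5, family="gamma")
        assert m2.alpha - m1.alpha == pytest.approx(np.log(7.5), abs=1e-6)
        np.testing.assert_allclose(m2.beta, m1.beta, atol=1e-6)

    def test_convergence_error_carries_trace(self):
        rng = np.random.default_rng(3)
        y = rng.lognormal(2, 1, 200)
        x = rng.normal(size=200)
        with pytest.raises(ConvergenceError) as ei:
            fit_glm_log(_design(pd.DataFrame({"x": x})), y,
                        family="inverse_gaussian", max_iter=1)
        assert isinstance(ei.value.trace, list)

    def test_sklearn_contract(self):
        from sklearn.base import clone
        est = GLMCostModel(family="poisson", max_iter=50)
        params = est.get_params()
        assert params["family"] == "poisson"
        clone(est)  # must be cloneable for model selection
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 2))
        y = np.exp(1 + X @ [0.3, -0.2]) * rng.gamma(5, 1 / 5, 200)
        est.fit(X, y)
        assert est.coef_.shape == (2,)
        assert est.predict(X).shape == (200,)
        assert est.score(X, y) > 0  # R^2 of a real fit


class TestLogOLS:
    def test_intercept_only_is_mean_log(self):
        y = np.array([1.0, 2.0, 4.0, 8.0])
        m = fit_log_ols(_intercept_only(4), y)
        assert m.alpha == pytest.approx(np.mean(np.log(y)), rel=1e-12)

    def test_matches_hand_normal_equations(self):
        # 5 rows, one binary covariate: group means solve the normal
        # equations exactly: alpha = mean(log y | x=0), beta = difference
        y = np.exp([0.0, 1.0, 1.0, 2.0, 3.0])
        x = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        m = fit_log_ols(_design(pd.DataFrame({"x": x})), y)
        assert m.alpha == pytest.approx(0.5, abs=1e-12)
        assert m.beta[0] == pytest.approx(1.5, abs=1e-12)

    def test_recovery_on_lognormal_world(self, lognormal_cohort):
        design, y = build_design(lognormal_cohort, "total")
        m = fit_log_ols(design, y)
        coef = dict(zip(m.column_names, m.params))
        assert abs(np.exp(coef["acrg3_6-2"]) - 20.0) / 20.0 < 0.10

    def test_mu_unset_until_retransformation(self):
        y = np.array([1.0, 2.0, 4.0, 8.0])
        m = fit_log_ols(_intercept_only(4), y)
        assert m.mu is None and m.resid_raw is None


class TestHuberWhite:
    def test_matches_textbook_hc0_on_six_rows(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.exp([0.1, 1.3, 1.9, 3.4, 3.9, 5.2])
        design = _design(pd.DataFrame({"x": x}))
        m = fit_log_ols(design, y)
        X = np.column_stack([np.ones(6), x])
        e = np.log(y) - X @ m.params
        bread = np.linalg.inv(X.T @ X)
        meat = sum(np.outer(X[i], X[i]) * e[i] ** 2 for i in range(6))
        expected = bread @ meat @ bread
        np.testing.assert_allclose(huber_white_vcov(m, design), expected,
                                   rtol=1e-10)

    def test_agrees_with_statsmodels_hc0(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=300)
        y = np.exp(1 + 0.5 * x + rng.normal(0, np.exp(0.4 * x)))
        design = _design(pd.DataFrame({"x": x}))
        m = fit_log_ols(design, y)
        sm_res = sm.OLS(np.log(y), design.exog).fit(cov_type="HC0")
        np.testing.assert_allclose(huber_white_vcov(m, design),
                                   sm_res.cov_params(), rtol=1e-8)

    def test_glm_sandwich_agrees_with_statsmodels(self, gamma_cohort):
        # statsmodels' HC0 bread is the observed Hessian; ours is the
        # expected information.  For the non-canonical log link they differ
        # by O(n^-1/2) relative terms, so agreement is close but not exact.
        design, y = build_design(gamma_cohort, "total")
        m = fit_glm_log(design, y, family="gamma")
        res = sm.GLM(y, design.exog,
                     family=sm.families.Gamma(sm.families.links.Log())
                     ).fit(cov_type="HC0")
        np.testing.assert_allclose(np.sqrt(np.diag(m.vcov_robust)),
                                   np.sqrt(np.diag(res.cov_params())),
                                   rtol=0.02)

    def test_collapses_to_model_vcov_under_homoscedasticity(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=10_000)
        y = np.exp(1 + 0.5 * x + rng.normal(0, 0.7, size=x.size))
        design = _design(pd.DataFrame({"x": x}))
        m = fit_log_ols(design, y)
        se_model = np.sqrt(np.diag(m.vcov_model))
        se_robust = np.sqrt(np.diag(huber_white_vcov(m, design)))
        np.testing.assert_allclose(se_robust, se_model, rtol=0.10)

    def test_robust_coverage_under_heteroscedasticity(self):
        # variance grows with x: robust intervals cover the truth at ~95%,
        # model-based intervals materially undercover
        rng = np.random.default_rng(10)
        beta_true = 0.5
        cover_rob = cover_mod = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(size=200)
            logy = 1 + beta_true * x + rng.normal(0, np.exp(0.7 * x))
            X = np.column_stack([np.ones(200), x])
            b = np.linalg.lstsq(X, logy, rcond=None)[0]
            e = logy - X @ b
            se_r = np.sqrt(ols_sandwich_vcov(X, e)[1, 1])
            s2 = e @ e / (200 - 2)
            se_m = np.sqrt((s2 * np.linalg.inv(X.T @ X))[1, 1])
            cover_rob += abs(b[1] - beta_true) < 1.96 * se_r
            cover_mod += abs(b[1] - beta_true) < 1.96 * se_m
        assert 0.90 <= cover_rob / reps <= 0.98
        assert cover_mod / reps < cover_rob / reps - 0.03


class TestVarianceModel:
    def _ols_fit(self, x, logy):
        design = _design(pd.DataFrame({"x": x}))
        return fit_log_ols(design, np.exp(logy)), design

    def test_homoscedastic_case_is_flat(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50_000)
        logy = 1 + 0.5 * x + rng.normal(0, 0.8, x.size)
        m, design = self._ols_fit(x, logy)
        vm = fit_variance_model(m, design)
        v = vm.predict_variance(design.exog)
        assert abs(vm.gamma[1]) < 0.05
        assert abs(v.mean() - m.resid_log.var()) / m.resid_log.var() < 0.05
        assert v.std() / v.mean() < 0.10

    def test_recovers_variance_ratio_between_categories(self):
        rng = np.random.default_rng(12)
        g = rng.random(50_000) < 0.5
        sd = np.where(g, 1.5, 0.5)
        logy = 2.0 + 0.3 * g + rng.normal(0, sd)
        design = _design(pd.DataFrame({"g": g.astype(float)}))
        m = fit_log_ols(design, np.exp(logy))
        vm = fit_variance_model(m, design)
        v1 = vm.predict_variance(np.array([[1.0, 1.0]]))[0]
        v0 = vm.predict_variance(np.array([[1.0, 0.0]]))[0]
        assert abs(v1 / v0 - 9.0) / 9.0 < 0.15

    def test_constant_magnitude_residuals_are_exact(self):
        resid = np.array([0.5, -0.5, 0.5, -0.5])
        exog = np.column_stack([np.ones(4), [0, 1, 0, 1]])
        vm = fit_variance_model_arrays(resid, exog)
        np.testing.assert_allclose(vm.predict_variance(exog), 0.25,
                                   rtol=1e-10)

    def test_zero_residuals_replaced_with_warning(self):
        resid = np.array([0.0, 0.5, -0.25, 0.75])
        exog = np.ones((4, 1))
        with pytest.warns(UserWarning, match="replaced 1 zero"):
            vm = fit_variance_model_arrays(resid, exog)
        assert vm.n_zero_replaced == 1
        assert np.all(vm.predict_variance(exog) > 0)


class TestPredictMean:
    def _logols_model(self, resid):
        n = len(resid)
        return FittedModel(
            branch="LOG_OLS", family=None, alpha=1.0, beta=np.array([]),
            vcov_model=np.eye(1), vcov_robust=np.eye(1),
            eta=np.ones(n), mu=None, resid_raw=None,
            resid_log=np.asarray(resid, dtype=float), n=n,
            column_names=("const",))

    def test_duan_factor_is_one_for_perfect_fit(self):
        m = self._logols_model([0.0, 0.0, 0.0, 0.0])
        pred = predict_mean(m, _intercept_only(4), method="duan")
        np.testing.assert_allclose(pred, np.exp(1.0), rtol=1e-12)

    def test_duan_factor_hand_value(self):
        m = self._logols_model([np.log(2.0), -np.log(2.0)])
        pred = predict_mean(m, _intercept_only(2), method="duan")
        np.testing.assert_allclose(pred, np.exp(1.0) * 1.25, rtol=1e-12)

    def test_duan_factor_at_least_one_when_residuals_centered(self):
        rng = np.random.default_rng(13)
        resid = rng.normal(size=101)
        resid -= resid.mean()
        m = self._logols_model(resid)
        pred = predict_mean(m, _intercept_only(101), method="duan")
        assert (pred / np.exp(1.0) >= 1.0).all()

    def test_method_branch_mismatch_raises(self, gamma_cohort):
        design, y = build_design(gamma_cohort, "total")
        glm = fit_glm_log(design, y, family="gamma")
        with pytest.raises(ValueError):
            predict_mean(glm, design, method="duan")
        ols = fit_log_ols(design, y)
        with pytest.raises(ValueError):
            predict_mean(ols, design, method="none")

    def test_normal_hetero_reduces_to_homoscedastic_factor(self):
        # intercept-only variance model must reproduce exp(sigma2/2)
        rng = np.random.default_rng(14)
        resid = rng.normal(0, 0.8, size=2_000)
        resid -= resid.mean()
        m = self._logols_model(resid)
        design = _intercept_only(len(resid))
        vm = fit_variance_model(m, design)
        pred = predict_mean(m, design, method="normal_hetero", varmodel=vm)
        sigma2 = np.mean(resid**2)
        np.testing.assert_allclose(pred, np.exp(1.0 + sigma2 / 2.0),
                                   rtol=1e-10)

    def test_hetero_lognormal_calibration(self):
        # heteroscedastic lognormal world: retransformed predictions match
        # observed means within 2%
        rng = np.random.default_rng(15)
        n = 50_000
        g = (rng.random(n) < 0.5).astype(float)
        sd = np.where(g == 1, 1.2, 0.5)
        logy = 3.0 + 0.8 * g + rng.normal(0, sd)
        y = np.exp(logy)
        est = LogOLSCostModel(retransform="normal_hetero")
        est.fit(pd.DataFrame({"g": g}), y)
        ratio = est.fitted_mean_.mean() / y.mean()
        assert 0.98 <= ratio <= 1.02
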