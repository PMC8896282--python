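import numpy as np
import pytest
from scipy.optimize import minimize

from areatrend.glm import (
    BinomialTrendGLM,
    SeparationError,
    empirical_logit,
    fit_logistic,
    residual_or,
    trend_or,
)
from areatrend.panel import ArealPanel
from areatrend.simulate import SimulationScenario, simulate_panel


def panel_one_cell(y, n):
    return ArealPanel(("A",), ("P1",), np.array([[y]]), np.array([[n]]), {})


def scipy_mle(panel, covariates=(), include_trend=True):
    """Independent optimizer of the same aggregated binomial likelihood."""
    from areatrend.glm import _design_matrix

    X, _ = _design_matrix(panel, covariates, include_trend)
    y = panel.y.ravel().astype(float)
    n = panel.n.ravel().astype(float)

    def nll(b):
        eta = X @ b
        return -np.sum(y * eta - n * np.logaddexp(0.0, eta))

    def grad(b):
        eta = X @ b
        p = 1 / (1 + np.exp(-eta))
        return -X.T @ (y - n * p)

    def hess(b):
        eta = X @ b
        p = 1 / (1 + np.exp(-eta))
        return X.T @ (X * (n * p * (1 - p))[:, None])

    res = minimize(nll, np.zeros(X.shape[1]), jac=grad, hess=hess,
                   method="trust-ncg", options={"gtol": 1e-12})
    return res.x


class TestFitLogistic:
    def test_intercept_only_single_cell(self):
        fit = BinomialTrendGLM(include_trend=False).fit(panel_one_cell(5, 10))
        assert fit.coef_["intercept"] == pytest.approx(0.0, abs=1e-10)
        assert fit.predict_proba(panel_one_cell(5, 10))[0, 0] == pytest.approx(0.5)

    def test_two_group_closed_form(self):
        # groups coded 0/1 with proportions 20/100 and 50/100: the saturated
        # MLE equals the empirical logits
        panel = ArealPanel(
            ("A", "B"), ("P1",),
            np.array([[20], [50]]), np.array([[100], [100]]),
            {"x": np.array([[0.0], [1.0]])},
        )
        fit = BinomialTrendGLM(covariates=("x",), include_trend=False).fit(panel)
        assert fit.coef_["intercept"] == pytest.approx(np.log(0.25), abs=1e-8)
        assert fit.coef_["x"] == pytest.approx(np.log(4.0), abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_optimizer(self, seed):
        panel, _ = simulate_panel(SimulationScenario(K=94, T=6, n_trials=80, seed=seed))
        fit = fit_logistic(panel, covariates=panel.covariate_names)
        expected = scipy_mle(panel, panel.covariate_names)
        np.testing.assert_allclose(fit.coef_.to_numpy(), expected, atol=1e-6)

    def test_matches_statsmodels(self, small_sim):
        import statsmodels.api as sm

        panel, _, _ = small_sim
        fit = fit_logistic(panel, covariates=panel.covariate_names)
        from areatrend.glm import _design_matrix

        X, _ = _design_matrix(panel, panel.covariate_names)
        endog = np.column_stack([panel.y.ravel(), (panel.n - panel.y).ravel()])
        sm_fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef_.to_numpy(), sm_fit.params, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov_)), sm_fit.bse, rtol=1e-4)

    def test_gradient_small_at_solution(self, small_sim):
        panel, _, _ = small_sim
        fit = fit_logistic(panel, covariates=panel.covariate_names)
        from areatrend.glm import _design_matrix

        X, _ = _design_matrix(panel, panel.covariate_names)
        p = 1 / (1 + np.exp(-(X @ fit.coef_.to_numpy())))
        grad = X.T @ (panel.y.ravel() - panel.n.ravel() * p)
        assert np.max(np.abs(grad)) < 1e-6

    def test_score_equation_reproduces_totals(self, small_sim):
        panel, _, _ = small_sim
        fit = fit_logistic(panel)
        fitted = fit.predict_proba(panel)
        assert np.sum(panel.n * fitted) == pytest.approx(panel.y.sum(), rel=1e-10)

    def test_nesting_loglik(self, small_sim):
        panel, _, _ = small_sim
        ll1 = fit_logistic(panel).loglik_
        ll2 = fit_logistic(panel, covariates=panel.covariate_names).loglik_
        assert ll2 >= ll1

    def test_covariance_symmetric_positive_definite(self, small_sim):
        panel, _, _ = small_sim
        fit = fit_logistic(panel, covariates=panel.covariate_names)
        np.testing.assert_allclose(fit.cov_, fit.cov_.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.cov_) > 0)

    def test_all_zero_outcome_raises(self):
        panel = ArealPanel(("A", "B"), ("P1", "P2"),
                           np.zeros((2, 2), dtype=int), np.full((2, 2), 10), {})
        with pytest.raises(SeparationError):
            fit_logistic(panel)

    def test_collinear_columns_named(self, small_sim):
        panel, _, _ = small_sim
        dup = dict(panel.covariates)
        dup["copy_of_age"] = dup["ami_age"].copy()
        p2 = ArealPanel(panel.unit_ids, panel.period_ids, panel.y, panel.n, dup)
        with pytest.raises(np.linalg.LinAlgError, match="copy_of_age"):
            fit_logistic(p2, covariates=p2.covariate_names)


class TestResidualOr:
    def test_exact_fit_gives_unit_or(self):
        # y=50, n=100, eta_hat=0: continuity corrections cancel exactly
        r = empirical_logit(50, 100) - 0.0
        assert np.exp(r) == pytest.approx(1.0)

    def test_doubled_odds(self):
        # y=40, n=60 against fitted p=0.5: (40.5/20.5) / 1
        r = empirical_logit(40, 60) - 0.0
        assert np.exp(r) == pytest.approx(40.5 / 20.5)

    def test_zero_cell_continuity_correction(self):
        r = empirical_logit(0, 10) - 0.0
        assert np.exp(r) == pytest.approx(0.5 / 10.5)

    def test_residual_table_contract(self, small_sim):
        panel, _, _ = small_sim
        fit = fit_logistic(panel, covariates=panel.covariate_names)
        tab = residual_or(panel, fit)
        assert len(tab) == panel.n_units * panel.n_periods
        assert np.all(tab["residual_or"] > 0)
        np.testing.assert_allclose(tab["residual_or"], np.exp(tab["residual"]))


class TestTrendOr:
    def test_null_trend_symmetric_ci(self):
        panel = ArealPanel(
            ("A", "B"), ("P1", "P2"),
            np.array([[5, 5], [5, 5]]), np.full((2, 2), 10), {},
        )
        fit = fit_logistic(panel)
        or_, lo, hi = trend_or(fit)
        assert or_ == pytest.approx(1.0, abs=1e-8)
        assert lo * hi == pytest.approx(1.0, rel=1e-6)

    def test_missing_trend_term_raises(self):
        fit = BinomialTrendGLM(include_trend=False).fit(panel_one_cell(5, 10))
        with pytest.raises(ValueError, match="period"):
            trend_or(fit)

    def test_recovery_across_replicates(self):
        # alpha = log(0.8), no random effects: the estimate should land in
        # (0.78, 0.82) nearly always at this sample size
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            panel, _ = simulate_panel(
                SimulationScenario(K=94, T=6, beta={}, alpha=np.log(0.8),
                                   tau2_phi=0.0, tau2_delta=0.0,
                                   n_trials=1000, seed=1000 + rep)
            )
            or_, _, _ = trend_or(fit_logistic(panel))
            hits += 0.78 < or_ < 0.82
        assert hits >= 0.9 * n_rep
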