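import numpy as np
import pytest
from scipy import stats

from areatrend.car import (
    ALT_PRIORS,
    CarLinearTrend,
    McmcSettings,
    PosteriorSamples,
    Priors,
    car_logdet,
    geweke_diagnostic,
    leroux_precision,
    model3_residuals,
    prior_sensitivity,
    run_mcmc,
    summarize_components,
    tau2_gibbs_draw,
)
from areatrend.panel import AdjacencyGraph, ArealPanel
from areatrend.simulate import lattice_graph, ring_graph, sample_car_field


def two_node_path():
    return AdjacencyGraph.from_edges(["A", "B"], [("A", "B")])


def three_node_path():
    return AdjacencyGraph.from_edges(["A", "B", "C"], [("A", "B"), ("B", "C")])


def make_samples(alpha_draws, phi=None, delta=None, K=3, S=None):
    S = len(alpha_draws) if S is None else S
    alpha = np.asarray(alpha_draws, dtype=float)
    return PosteriorSamples(
        term_names=("intercept",),
        unit_ids=tuple(f"U{i}" for i in range(K)),
        beta=np.zeros((S, 1)),
        alpha=alpha,
        phi=np.zeros((S, K)) if phi is None else phi,
        delta=np.zeros((S, K)) if delta is None else delta,
        tau2_phi=np.full(S, 0.1),
        tau2_delta=np.full(S, 0.01),
        rho_phi=np.full(S, 0.5),
        rho_delta=np.full(S, 0.5),
        log_post=np.zeros(S),
        acceptance={},
        settings=McmcSettings(n_iterations=2000, burn_in=500, thin=1),
        priors=Priors(),
    )


class TestLerouxPrecision:
    def test_independence_limit(self, path4):
        Q = leroux_precision(path4, rho=0.0, tau2=2.0)
        np.testing.assert_allclose(Q, np.eye(4) / 2.0)

    def test_intrinsic_limit_two_nodes(self):
        Q = leroux_precision(two_node_path(), rho=1.0, tau2=1.0)
        np.testing.assert_allclose(Q, [[1, -1], [-1, 1]])
        assert abs(np.linalg.det(Q)) < 1e-12

    def test_three_node_path_half_rho(self):
        Q = leroux_precision(three_node_path(), rho=0.5, tau2=1.0)
        expected = [[1.0, -0.5, 0.0], [-0.5, 1.5, -0.5], [0.0, -0.5, 1.0]]
        np.testing.assert_allclose(Q, expected)


class TestCarLogdet:
    def test_rho_zero_is_zero(self, dk94):
        assert car_logdet(dk94, 0.0) == 0.0

    def test_two_node_closed_form(self):
        # eigenvalues of D - W are (0, 2): rho=0.5 gives log 0.5 + log 1.5
        assert car_logdet(two_node_path(), 0.5) == pytest.approx(np.log(0.5) + np.log(1.5))

    def test_matches_dense_logdet(self, dk94):
        rho = 0.3
        M = rho * (np.diag(dk94.degrees) - dk94.W) + (1 - rho) * np.eye(94)
        sign, dense = np.linalg.slogdet(M)
        assert sign == 1.0
        assert car_logdet(dk94, rho) == pytest.approx(dense, abs=1e-8)

    def test_intrinsic_limit_flags_minus_inf(self):
        with pytest.warns(UserWarning, match="singular"):
            assert car_logdet(two_node_path(), 1.0) == -np.inf


class TestTau2Gibbs:
    def test_conditional_mean_matches_conjugacy(self):
        # quadratic form 4, K=10, prior (1, 0.01): conditional IG(6, 2.01),
        # mean 2.01/5 = 0.402
        graph = ring_graph(10)
        field = np.zeros(10)
        field[0] = 2.0  # rho=0 makes the quadratic form |phi|^2 = 4
        rng = np.random.default_rng(0)
        draws = np.array(
            [tau2_gibbs_draw(field, graph, 0.0, Priors(), rng) for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(0.402, abs=0.01)

    def test_draws_match_analytic_inverse_gamma(self):
        graph = lattice_graph(16)
        rng_field = np.random.default_rng(1)
        field = rng_field.standard_normal(16) * 0.3
        rho = 0.6
        L = np.diag(graph.degrees) - graph.W
        quad = rho * field @ L @ field + (1 - rho) * field @ field
        pri = Priors()
        rng = np.random.default_rng(2)
        draws = np.array(
            [tau2_gibbs_draw(field, graph, rho, pri, rng) for _ in range(10_000)]
        )
        dist = stats.invgamma(a=pri.tau2_shape + 8, scale=pri.tau2_scale + quad / 2)
        assert stats.kstest(draws, dist.cdf).pvalue > 0.001


class TestGeweke:
    def test_null_rarely_flags(self):
        rng = np.random.default_rng(4)
        flags = 0
        n_rep = 500
        for _ in range(n_rep):
            z = geweke_diagnostic(rng.standard_normal(10_000))
            flags += abs(z) >= 3
        assert flags / n_rep < 0.01

    def test_constructed_drift_flags_hard(self):
        rng = np.random.default_rng(5)
        chain = np.r_[np.zeros(500), np.ones(500)] + 1e-6 * rng.standard_normal(1000)
        assert abs(geweke_diagnostic(chain)) > 10

    def test_constant_chain_errors(self):
        with pytest.raises(ValueError, match="variance"):
            geweke_diagnostic(np.ones(1000))

    def test_short_chain_errors(self):
        with pytest.raises(ValueError, match="short"):
            geweke_diagnostic(np.random.default_rng(0).standard_normal(100))


class TestSummaries:
    def test_degenerate_alpha_draws_anchor_trend_or(self):
        s = make_samples(np.full(300, np.log(0.788)))
        out = summarize_components(s)
        assert out.trend_or == pytest.approx(0.788)
        assert out.trend_ci == (pytest.approx(0.788), pytest.approx(0.788))

    def test_symmetric_delta_gives_unit_temporal_or(self):
        rng = np.random.default_rng(6)
        draws = rng.standard_normal((4000, 3)) * 0.2
        s = make_samples(np.zeros(4000), delta=draws)
        out = summarize_components(s)
        np.testing.assert_allclose(out.unit_table["temporal_or"], 1.0, atol=0.02)

    def test_three_point_median(self):
        draws = np.array([np.log(1), np.log(2), np.log(3)] * 100)
        out = summarize_components(make_samples(draws))
        assert out.trend_or == pytest.approx(2.0)

    def test_bounds_ordering(self):
        rng = np.random.default_rng(7)
        s = make_samples(rng.standard_normal(500),
                         phi=rng.standard_normal((500, 3)),
                         delta=rng.standard_normal((500, 3)))
        t = summarize_components(s).unit_table
        assert (t["spatial_lo"] <= t["spatial_or"]).all()
        assert (t["spatial_or"] <= t["spatial_hi"]).all()
        assert (t[["temporal_lo", "temporal_or", "temporal_hi"]] > 0).all().all()


class TestSampler:
    def test_deterministic_given_seed(self, small_sim):
        panel, graph, _ = small_sim
        settings = McmcSettings(n_iterations=2600, burn_in=600, thin=10, seed=99)
        s1 = run_mcmc(panel, graph, settings=settings)
        s2 = run_mcmc(panel, graph, settings=settings)
        np.testing.assert_array_equal(s1.alpha, s2.alpha)
        np.testing.assert_array_equal(s1.phi, s2.phi)
        np.testing.assert_array_equal(s1.tau2_delta, s2.tau2_delta)

    def test_retained_draws_recentred(self, small_sim):
        panel, graph, _ = small_sim
        s = run_mcmc(panel, graph,
                     settings=McmcSettings(n_iterations=1600, burn_in=400, thin=10, seed=3))
        np.testing.assert_allclose(s.phi.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(s.delta.mean(axis=1), 0.0, atol=1e-12)

    def test_log_posterior_stationary_after_burnin(self, small_sim):
        panel, graph, _ = small_sim
        s = run_mcmc(panel, graph,
                     settings=McmcSettings(n_iterations=4600, burn_in=2600, thin=10, seed=12))
        assert abs(geweke_diagnostic(s.log_post)) < 3

    def test_too_few_retained_errors(self, small_sim):
        panel, graph, _ = small_sim
        with pytest.raises(ValueError, match="100"):
            run_mcmc(panel, graph,
                     settings=McmcSettings(n_iterations=600, burn_in=400, thin=10))

    def test_estimator_interface(self, small_sim):
        panel, graph, _ = small_sim
        est = CarLinearTrend(covariates=panel.covariate_names, n_iterations=1600,
                             burn_in=400, thin=10, seed=5)
        assert est.get_params()["seed"] == 5
        est.fit(panel, graph)
        assert est.samples_.n_retained == 120
        assert est.summary_.trend_or > 0
        res = est.residuals(panel)
        assert res.shape == (panel.n_units, panel.n_periods)

    def test_prior_only_matches_direct_car_draws(self):
        # with no data (all trial counts 0) and fixed hyperparameters the
        # phi marginals must match the centred Leroux CAR prior
        graph = lattice_graph(36)
        panel = ArealPanel(graph.unit_ids, ("P1",),
                           np.zeros((36, 1), dtype=int), np.zeros((36, 1), dtype=int), {})
        rho, tau2 = 0.7, 0.5
        s = run_mcmc(
            panel, graph, covariates=(),
            settings=McmcSettings(n_iterations=21_000, burn_in=1000, thin=20, seed=8),
            sample_tau2=False, sample_rho=False,
            initial_state={"tau2_phi": tau2, "tau2_delta": tau2,
                           "rho_phi": rho, "rho_delta": rho},
        )
        rng = np.random.default_rng(9)
        direct = np.array(
            [sample_car_field(graph, rho, tau2, rng) for _ in range(4000)]
        )
        var_mcmc = s.phi.var(axis=0).mean()
        var_direct = direct.var(axis=0).mean()
        assert var_mcmc == pytest.approx(var_direct, rel=0.2)
        edges_idx = [(graph.index_of(a), graph.index_of(b)) for a, b in graph.edges]

        def edge_corr(draws):
            num = np.mean([np.mean(draws[:, i] * draws[:, j]) for i, j in edges_idx])
            return num / draws.var(axis=0).mean()

        assert edge_corr(s.phi) == pytest.approx(edge_corr(direct), abs=0.1)


class TestModel3Residuals:
    def test_exact_model_gives_near_zero_residuals(self):
        K, T = 4, 3
        graph = ring_graph(K)
        beta0, alpha = -0.4, np.log(0.85)
        t_p = np.arange(1, T + 1) - (T + 1) / 2
        eta = beta0 + alpha * t_p[None, :] * np.ones((K, 1))
        n = np.full((K, T), 2_000_000)
        y = np.rint(n / (1 + np.exp(-eta))).astype(int)
        panel = ArealPanel(graph.unit_ids, tuple(f"P{j}" for j in range(T)), y, n, {})
        s = make_samples(np.full(200, alpha), K=K)
        s.beta[:, 0] = beta0
        res = model3_residuals(panel, s)
        assert np.max(np.abs(res)) < 1e-3

    def test_single_period_panel(self):
        graph = ring_graph(4)
        panel = ArealPanel(graph.unit_ids, ("P1",),
                           np.array([[3], [4], [5], [2]]), np.full((4, 1), 10), {})
        s = make_samples(np.zeros(200), K=4)
        res = model3_residuals(panel, s)
        assert res.shape == (4, 1)
        assert np.all(np.isfinite(res))


class TestPriorSensitivity:
    def test_identical_priors_differ_only_by_monte_carlo_error(self, small_sim):
        panel, graph, _ = small_sim
        settings = McmcSettings(n_iterations=3600, burn_in=1600, thin=10, seed=21)
        out = prior_sensitivity(panel, graph, settings, priors_a=Priors(), priors_b=Priors())
        assert out["trend_log_or_diff"] < 0.02

    def test_tiny_panel_robustness(self):
        graph = ring_graph(5)
        rng = np.random.default_rng(13)
        n = np.full((5, 2), 5)
        y = rng.binomial(n, 0.4)
        panel = ArealPanel(graph.unit_ids, ("P1", "P2"), y, n, {})
        settings = McmcSettings(n_iterations=1600, burn_in=400, thin=10, seed=2)
        out = prior_sensitivity(panel, graph, settings, priors_b=ALT_PRIORS)
        assert np.isfinite(out["trend_log_or_diff"])
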