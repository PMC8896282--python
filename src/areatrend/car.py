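"""Bayesian spatio-temporal binomial model with Leroux-CAR random effects.

The model ("Model 3") extends the covariate-adjusted trend GLM with two
spatially autocorrelated random effects — a spatial structure component
phi_k (the unit's mortality level at the centred time point, relative to
the national mean) and a temporal structure component delta_k (how the
unit's linear trend deviates from the national trend alpha):

    logit p_kt = x_kt' beta + phi_k + (alpha + delta_k) * t_p
    y_kt ~ Binomial(n_kt, p_kt)

Both random-effect vectors get the Leroux conditional autoregressive prior
with precision Q = [rho (D - W) + (1 - rho) I] / tau^2, which interpolates
between independence (rho = 0) and the intrinsic CAR (rho -> 1).  Inference
is Metropolis-within-Gibbs: random-walk Metropolis for beta, alpha, the
single-site phi_k and delta_k (vectorized over graph-colouring classes,
which leaves the kernel identical to sequential single-site updates), a
conjugate inverse-gamma Gibbs draw for each tau^2, and logit-scale
random-walk Metropolis for each rho using cached eigenvalues of D - W for
the determinant term.  After every sweep phi and delta are re-centred, their
means absorbed into the intercept and alpha, which pins down the otherwise
unidentified overall level and national trend.

Draw order per sweep (one generator stream, fixed for reproducibility):
beta elementwise, alpha, phi by colour class, delta by colour class,
tau2_phi, tau2_delta, rho_phi, rho_delta, then the deterministic
re-centring.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .glm import BinomialTrendGLM, SeparationError, _log1pexp, logit_residuals
from .panel import AdjacencyGraph, ArealPanel


@dataclass(frozen=True)
class Priors:
    """Hyperpriors: tau^2 ~ InvGamma(shape, scale); beta, alpha ~ N(0, var)."""

    tau2_shape: float = 1.0
    tau2_scale: float = 0.01
    coef_var: float = 100_000.0

    def __post_init__(self) -> None:
        if self.tau2_shape <= 0 or self.tau2_scale <= 0 or self.coef_var <= 0:
            raise ValueError("prior hyperparameters must be positive")


#: Alternative prior set used for the sensitivity analysis.
ALT_PRIORS = Priors(tau2_shape=0.5, tau2_scale=0.005, coef_var=200_000.0)


@dataclass(frozen=True)
class McmcSettings:
    """Chain schedule.  The desk-scale default retains
    (26000 - 6000) / 10 = 2000 draws; ``full_scale`` retains 20000."""

    n_iterations: int = 26_000
    burn_in: int = 6_000
    thin: int = 10
    seed: int = 0
    adapt_interval: int = 100

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @classmethod
    def full_scale(cls, seed: int = 0) -> "McmcSettings":
        """Long production schedule (1.05M iterations, 20,000 retained)."""
        return cls(n_iterations=1_050_000, burn_in=50_000, thin=50, seed=seed)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus acceptance diagnostics."""

    term_names: tuple[str, ...]
    unit_ids: tuple[str, ...]
    beta: np.ndarray       # S x p
    alpha: np.ndarray      # S
    phi: np.ndarray        # S x K
    delta: np.ndarray      # S x K
    tau2_phi: np.ndarray   # S
    tau2_delta: np.ndarray
    rho_phi: np.ndarray
    rho_delta: np.ndarray
    log_post: np.ndarray
    acceptance: dict[str, float]
    settings: McmcSettings
    priors: Priors

    @property
    def n_retained(self) -> int:
        return self.alpha.shape[0]


@dataclass(frozen=True)
class ComponentSummary:
    """Posterior OR summaries for mapping and reporting.

    ``unit_table`` has, per unit, the spatial and temporal structure
    component ORs (posterior medians of exp(phi_k) and exp(delta_k)) with
    equal-tailed 95% credible bounds and the credible-interval span (the
    certainty-map quantity).  A temporal OR above 1 means the unit's
    mortality declined slower than the national trend.
    """

    unit_table: pd.DataFrame
    trend_or: float
    trend_ci: tuple[float, float]
    trend_or_mean: float
    covariate_table: pd.DataFrame


def leroux_precision(graph: AdjacencyGraph, rho: float, tau2: float) -> np.ndarray:
    """Leroux CAR precision Q = [rho (D - W) + (1 - rho) I] / tau2.

    Positive definite for rho < 1; at rho = 1 it is the (singular)
    intrinsic-CAR precision.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if tau2 <= 0:
        raise ValueError(f"tau2 must be > 0, got {tau2}")
    K = graph.n_units
    L = np.diag(graph.degrees) - graph.W
    return (rho * L + (1.0 - rho) * np.eye(K)) / tau2


def laplacian_eigenvalues(graph: AdjacencyGraph) -> np.ndarray:
    """Eigenvalues of D - W (symmetric; computed once and cached by callers)."""
    L = np.diag(graph.degrees) - graph.W
    return np.linalg.eigvalsh(L)


def car_logdet(
    graph: AdjacencyGraph | np.ndarray, rho: float
) -> float:
    """log det [rho (D - W) + (1 - rho) I] via Laplacian eigenvalues.

    Accepts either a graph or precomputed eigenvalues of D - W.  Returns
    -inf (with a warning) at rho = 1 on a graph with a zero eigenvalue,
    i.e. the intrinsic-CAR limit.
    """
    lam = (
        graph
        if isinstance(graph, np.ndarray)
        else laplacian_eigenvalues(graph)
    )
    vals = rho * lam + (1.0 - rho)
    if np.any(vals <= 0):
        warnings.warn("singular CAR precision (rho at or beyond 1)", stacklevel=2)
        return -np.inf
    return float(np.sum(np.log(vals)))


def _colour_classes(graph: AdjacencyGraph) -> list[np.ndarray]:
    """Partition unit indices into independent sets (greedy colouring)."""
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_units))
    for a, b in graph.edges:
        g.add_edge(graph.index_of(a), graph.index_of(b))
    colours = nx.greedy_color(g, strategy="largest_first")
    n_col = max(colours.values()) + 1
    return [
        np.array(sorted(k for k, c in colours.items() if c == col), dtype=np.intp)
        for col in range(n_col)
    ]


def tau2_gibbs_draw(
    field: np.ndarray,
    graph: AdjacencyGraph,
    rho: float,
    priors: Priors,
    rng: np.random.Generator,
) -> float:
    """Conjugate inverse-gamma draw for a CAR variance.

    Conditional on the field u, tau^2 ~ InvGamma(a + K/2, b + u'Ru/2) with
    R = rho (D - W) + (1 - rho) I.
    """
    K = field.shape[0]
    L = np.diag(graph.degrees) - graph.W
    quad = rho * field @ L @ field + (1.0 - rho) * field @ field
    shape = priors.tau2_shape + K / 2.0
    scale = priors.tau2_scale + quad / 2.0
    return float(scale / rng.gamma(shape))


class _CarSampler:
    """One MCMC run; holds precomputed structures and the mutable state."""

    TARGET_ACCEPT = 0.4

    def __init__(
        self,
        panel: ArealPanel,
        graph: AdjacencyGraph,
        priors: Priors,
        settings: McmcSettings,
        covariates: tuple[str, ...],
        sample_tau2: bool = True,
        sample_rho: bool = True,
        initial_state: dict | None = None,
    ):
        if tuple(panel.unit_ids) != tuple(graph.unit_ids):
            raise ValueError("panel and graph must share the same ordered unit labels")
        if settings.n_retained < 100:
            raise ValueError(
                f"settings retain only {settings.n_retained} draws; need >= 100"
            )
        if graph.n_components > 1:
            warnings.warn("graph is disconnected; CAR smoothing acts per component",
                          stacklevel=3)
        self.panel = panel
        self.graph = graph
        self.priors = priors
        self.settings = settings
        self.sample_tau2 = sample_tau2
        self.sample_rho = sample_rho

        K, T = panel.n_units, panel.n_periods
        self.y = panel.y.astype(float)
        self.n = panel.n.astype(float)
        if self.n.sum() > 0 and (self.y.sum() == 0 or (self.n - self.y).sum() == 0):
            raise SeparationError("outcome is all-zero or all-trials")
        self.t_p = panel.t_p
        self.t_row = np.broadcast_to(self.t_p, (K, T))
        self.W = graph.W
        self.d = graph.degrees
        self.L = np.diag(self.d) - self.W
        self.lam = np.linalg.eigvalsh(self.L)
        self.colours = _colour_classes(graph)

        self.term_names = ("intercept",) + tuple(covariates)
        cols = [np.ones((K, T))]
        for name in covariates:
            cols.append(panel.covariates[name])
        self.Xcols = cols  # list of K x T arrays, one per beta term
        self.p = len(cols)

        # initial state from the covariate-adjusted GLM when it exists
        beta = np.zeros(self.p)
        alpha = 0.0
        beta_scale = np.full(self.p, 0.1)
        alpha_scale = 0.1
        try:
            glm = BinomialTrendGLM(covariates=covariates).fit(panel)
            coefs = glm.coef_
            beta[0] = coefs["intercept"]
            alpha = float(coefs["t_p"])
            ses = np.sqrt(np.diag(glm.cov_))
            order = list(coefs.index)
            beta_scale[0] = 2.4 * ses[order.index("intercept")]
            alpha_scale = 2.4 * ses[order.index("t_p")]
            for j, name in enumerate(covariates, start=1):
                beta[j] = coefs[name]
                beta_scale[j] = 2.4 * ses[order.index(name)]
        except (SeparationError, np.linalg.LinAlgError):
            pass

        self.state = {
            "beta": beta,
            "alpha": alpha,
            "phi": np.zeros(K),
            "delta": np.zeros(K),
            "tau2_phi": 0.01,
            "tau2_delta": 0.01,
            "rho_phi": 0.5,
            "rho_delta": 0.5,
        }
        if initial_state:
            self.state.update(initial_state)

        self.scales = {
            "beta": beta_scale,
            "alpha": alpha_scale,
            "phi": np.full(K, 0.1),
            "delta": np.full(K, 0.05),
            "rho_phi": 0.5,
            "rho_delta": 0.5,
        }
        self.eta = self._eta_from_state()

    # --- likelihood helpers -------------------------------------------------

    def _eta_from_state(self) -> np.ndarray:
        s = self.state
        eta = sum(c * b for c, b in zip(self.Xcols, s["beta"]))
        return eta + s["phi"][:, None] + (s["alpha"] + s["delta"][:, None]) * self.t_p

    def _ll_delta_full(self, d_eta: np.ndarray) -> float:
        eta_new = self.eta + d_eta
        return float(
            np.sum(self.y * d_eta - self.n * (_log1pexp(eta_new) - _log1pexp(self.eta)))
        )

    def _ll_delta_rows(self, idx: np.ndarray, d_eta_rows: np.ndarray) -> np.ndarray:
        eta_old = self.eta[idx]
        eta_new = eta_old + d_eta_rows
        return np.sum(
            self.y[idx] * d_eta_rows
            - self.n[idx] * (_log1pexp(eta_new) - _log1pexp(eta_old)),
            axis=1,
        )

    def _log_posterior(self) -> float:
        s = self.state
        ll = float(np.sum(self.y * self.eta - self.n * _log1pexp(self.eta)))
        v = self.priors.coef_var
        lp = -0.5 * (np.sum(s["beta"] ** 2) + s["alpha"] ** 2) / v
        for f, rho, tau2 in (
            (s["phi"], s["rho_phi"], s["tau2_phi"]),
            (s["delta"], s["rho_delta"], s["tau2_delta"]),
        ):
            quad = rho * f @ self.L @ f + (1.0 - rho) * f @ f
            K = f.shape[0]
            lp += 0.5 * car_logdet(self.lam, rho) - 0.5 * K * np.log(tau2) - quad / (2 * tau2)
            a, b = self.priors.tau2_shape, self.priors.tau2_scale
            lp += -(a + 1.0) * np.log(tau2) - b / tau2
        return ll + lp

    # --- update blocks ------------------------------------------------------

    def _update_coef(self, rng) -> int:
        s, acc = self.state, 0
        v = self.priors.coef_var
        for j in range(self.p):
            z = rng.standard_normal()
            u = rng.random()
            step = self.scales["beta"][j] * z
            d_eta = self.Xcols[j] * step
            b_old = s["beta"][j]
            b_new = b_old + step
            log_r = self._ll_delta_full(d_eta) - (b_new**2 - b_old**2) / (2 * v)
            if np.log(u) < log_r:
                s["beta"][j] = b_new
                self.eta += d_eta
                acc += 1
                self._acc["beta"][j] += 1
            self._att["beta"][j] += 1
        return acc

    def _update_alpha(self, rng) -> None:
        s = self.state
        z, u = rng.standard_normal(), rng.random()
        step = self.scales["alpha"] * z
        d_eta = self.t_row * step
        a_old, a_new = s["alpha"], s["alpha"] + step
        v = self.priors.coef_var
        log_r = self._ll_delta_full(d_eta) - (a_new**2 - a_old**2) / (2 * v)
        if np.log(u) < log_r:
            s["alpha"] = a_new
            self.eta += d_eta
            self._acc["alpha"] += 1
        self._att["alpha"] += 1

    def _update_field(self, name: str, rng) -> None:
        """Single-site Metropolis for phi or delta, one colour class at a time.

        The full-conditional prior for site k given its neighbours is
        N(rho * sum_j w_kj u_j / (rho d_k + 1 - rho),
          tau2 / (rho d_k + 1 - rho)).
        """
        s = self.state
        field = s[name]
        rho = s["rho_phi" if name == "phi" else "rho_delta"]
        tau2 = s["tau2_phi" if name == "phi" else "tau2_delta"]
        prior_prec = (rho * self.d + 1.0 - rho) / tau2
        for idx in self.colours:
            z = rng.standard_normal(idx.size)
            u = rng.random(idx.size)
            step = self.scales[name][idx] * z
            old = field[idx]
            new = old + step
            m = rho * (self.W[idx] @ field) / (rho * self.d[idx] + 1.0 - rho)
            d_prior = -0.5 * prior_prec[idx] * ((new - m) ** 2 - (old - m) ** 2)
            if name == "phi":
                d_eta_rows = step[:, None] * np.ones((1, self.eta.shape[1]))
            else:
                d_eta_rows = step[:, None] * self.t_p[None, :]
            d_ll = self._ll_delta_rows(idx, d_eta_rows)
            accept = np.log(u) < d_ll + d_prior
            if np.any(accept):
                rows = idx[accept]
                field[rows] = new[accept]
                self.eta[rows] += d_eta_rows[accept]
            self._acc[name][idx] += accept
            self._att[name][idx] += 1

    def _update_tau2(self, name: str, rng) -> None:
        s = self.state
        field = s["phi" if name == "tau2_phi" else "delta"]
        rho = s["rho_phi" if name == "tau2_phi" else "rho_delta"]
        quad = rho * field @ self.L @ field + (1.0 - rho) * field @ field
        shape = self.priors.tau2_shape + field.shape[0] / 2.0
        scale = self.priors.tau2_scale + quad / 2.0
        s[name] = float(scale / rng.gamma(shape))

    def _update_rho(self, name: str, rng) -> None:
        s = self.state
        field = s["phi" if name == "rho_phi" else "delta"]
        tau2 = s["tau2_phi" if name == "rho_phi" else "tau2_delta"]
        rho_old = s[name]
        z, u = rng.standard_normal(), rng.random()
        theta_new = logit(rho_old) + self.scales[name] * z
        rho_new = float(np.clip(expit(theta_new), 1e-12, 1.0 - 1e-12))
        quad_L = field @ self.L @ field
        quad_I = field @ field

        def log_target(rho):
            quad = rho * quad_L + (1.0 - rho) * quad_I
            # uniform prior on rho; logit-scale proposal adds log|drho/dtheta|
            return (
                0.5 * car_logdet(self.lam, rho)
                - quad / (2.0 * tau2)
                + np.log(rho)
                + np.log1p(-rho)
            )

        log_r = log_target(rho_new) - log_target(rho_old)
        if np.log(u) < log_r:
            s[name] = rho_new
            self._acc[name] += 1
        self._att[name] += 1

    def _recentre(self) -> None:
        s = self.state
        m_phi = s["phi"].mean()
        s["phi"] -= m_phi
        s["beta"][0] += m_phi
        m_delta = s["delta"].mean()
        s["delta"] -= m_delta
        s["alpha"] += m_delta
        # eta is unchanged: the means move between exactly-compensating terms

    def _adapt(self) -> None:
        for key in ("beta", "alpha", "phi", "delta", "rho_phi", "rho_delta"):
            att = self._att[key]
            acc = self._acc[key]
            rate = np.where(np.asarray(att) > 0, np.asarray(acc) / np.maximum(att, 1), self.TARGET_ACCEPT)
            factor = np.exp(np.clip(rate - self.TARGET_ACCEPT, -0.5, 0.5))
            self.scales[key] = np.clip(self.scales[key] * factor, 1e-4, 10.0)
            self._acc[key] = np.zeros_like(np.asarray(acc, dtype=float)) if np.ndim(acc) else 0.0
            self._att[key] = np.zeros_like(np.asarray(att, dtype=float)) if np.ndim(att) else 0.0

    def _reset_counters(self) -> None:
        K = self.graph.n_units
        self._acc = {
            "beta": np.zeros(self.p),
            "alpha": 0.0,
            "phi": np.zeros(K),
            "delta": np.zeros(K),
            "rho_phi": 0.0,
            "rho_delta": 0.0,
        }
        self._att = {
            "beta": np.zeros(self.p),
            "alpha": 0.0,
            "phi": np.zeros(K),
            "delta": np.zeros(K),
            "rho_phi": 0.0,
            "rho_delta": 0.0,
        }

    # --- main loop ----------------------------------------------------------

    def run(self) -> PosteriorSamples:
        st = self.settings
        rng = np.random.default_rng(st.seed)
        K = self.graph.n_units
        S = st.n_retained
        out = {
            "beta": np.empty((S, self.p)),
            "alpha": np.empty(S),
            "phi": np.empty((S, K)),
            "delta": np.empty((S, K)),
            "tau2_phi": np.empty(S),
            "tau2_delta": np.empty(S),
            "rho_phi": np.empty(S),
            "rho_delta": np.empty(S),
            "log_post": np.empty(S),
        }
        self._reset_counters()
        kept = 0
        for it in range(1, st.n_iterations + 1):
            self._update_coef(rng)
            self._update_alpha(rng)
            self._update_field("phi", rng)
            self._update_field("delta", rng)
            if self.sample_tau2:
                self._update_tau2("tau2_phi", rng)
                self._update_tau2("tau2_delta", rng)
            if self.sample_rho:
                self._update_rho("rho_phi", rng)
                self._update_rho("rho_delta", rng)
            self._recentre()

            if it <= st.burn_in:
                if it % st.adapt_interval == 0:
                    self._adapt()
                if it == st.burn_in:
                    self._reset_counters()  # acceptance reported post burn-in
            elif (it - st.burn_in) % st.thin == 0 and kept < S:
                s = self.state
                out["beta"][kept] = s["beta"]
                out["alpha"][kept] = s["alpha"]
                out["phi"][kept] = s["phi"]
                out["delta"][kept] = s["delta"]
                out["tau2_phi"][kept] = s["tau2_phi"]
                out["tau2_delta"][kept] = s["tau2_delta"]
                out["rho_phi"][kept] = s["rho_phi"]
                out["rho_delta"][kept] = s["rho_delta"]
                out["log_post"][kept] = self._log_posterior()
                kept += 1

        post = st.n_iterations - st.burn_in
        acceptance = {
            "beta": float(np.mean(self._acc["beta"] / np.maximum(self._att["beta"], 1))),
            "alpha": float(self._acc["alpha"] / max(self._att["alpha"], 1)),
            "phi": float(np.mean(self._acc["phi"] / np.maximum(self._att["phi"], 1))),
            "delta": float(np.mean(self._acc["delta"] / np.maximum(self._att["delta"], 1))),
            "rho_phi": float(self._acc["rho_phi"] / max(self._att["rho_phi"], 1)),
            "rho_delta": float(self._acc["rho_delta"] / max(self._att["rho_delta"], 1)),
        }
        assert post >= 1
        return PosteriorSamples(
            term_names=self.term_names,
            unit_ids=self.panel.unit_ids,
            beta=out["beta"][:kept],
            alpha=out["alpha"][:kept],
            phi=out["phi"][:kept],
            delta=out["delta"][:kept],
            tau2_phi=out["tau2_phi"][:kept],
            tau2_delta=out["tau2_delta"][:kept],
            rho_phi=out["rho_phi"][:kept],
            rho_delta=out["rho_delta"][:kept],
            log_post=out["log_post"][:kept],
            acceptance=acceptance,
            settings=st,
            priors=self.priors,
        )


class CarLinearTrend(BaseEstimator):
    """Leroux-CAR spatio-temporal model with spatially varying linear trends.

    scikit-learn-style estimator: ``fit(panel, graph)`` runs the
    Metropolis-within-Gibbs sampler and exposes the retained posterior in
    ``samples_`` with OR summaries in ``summary_``.

    Parameters
    ----------
    covariates :
        Unit-period covariate names entering the fixed effects (the adjusted
        model uses the panel's five sociodemographic columns; empty tuple
        fits trend + random effects only).
    priors :
        Hyperpriors; defaults InvGamma(1, 0.01) on the CAR variances and
        N(0, 1e5) on the fixed effects.
    n_iterations, burn_in, thin, seed, adapt_interval :
        Chain schedule (desk-scale default 26000/6000/10 retains 2000 draws).
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = (),
        priors: Priors = Priors(),
        n_iterations: int = 26_000,
        burn_in: int = 6_000,
        thin: int = 10,
        seed: int = 0,
        adapt_interval: int = 100,
    ):
        self.covariates = covariates
        self.priors = priors
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.adapt_interval = adapt_interval

    def fit(self, panel: ArealPanel, graph: AdjacencyGraph) -> "CarLinearTrend":
        settings = McmcSettings(
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            adapt_interval=self.adapt_interval,
        )
        self.samples_ = _CarSampler(
            panel, graph, self.priors, settings, tuple(self.covariates)
        ).run()
        self.summary_ = summarize_components(self.samples_)
        self.acceptance_ = self.samples_.acceptance
        return self

    def residuals(self, panel: ArealPanel) -> np.ndarray:
        return model3_residuals(panel, self.samples_)


def run_mcmc(
    panel: ArealPanel,
    graph: AdjacencyGraph,
    priors: Priors = Priors(),
    settings: McmcSettings = McmcSettings(),
    covariates: tuple[str, ...] | None = None,
    sample_tau2: bool = True,
    sample_rho: bool = True,
    initial_state: dict | None = None,
) -> PosteriorSamples:
    """Run the Metropolis-within-Gibbs sampler and return retained draws.

    ``covariates=None`` uses every covariate the panel carries.  The
    ``sample_tau2`` / ``sample_rho`` switches and ``initial_state`` exist
    for diagnostics (e.g. prior-only sampling at fixed hyperparameters).
    """
    if covariates is None:
        covariates = panel.covariate_names
    sampler = _CarSampler(
        panel,
        graph,
        priors,
        settings,
        tuple(covariates),
        sample_tau2=sample_tau2,
        sample_rho=sample_rho,
        initial_state=initial_state,
    )
    return sampler.run()


def geweke_diagnostic(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence Z-score for one chain of retained draws.

    Compares the mean of the first 10% with the mean of the last 50%,
    standardized by batch-means estimates of each segment-mean variance
    (about sqrt(m) batches for a segment of length m).  |Z| > 2 suggests
    the chain had not reached its stationary distribution.
    """
    chain = np.asarray(chain, dtype=float)
    n = chain.shape[0]
    if n < 200:
        raise ValueError(f"chain too short for the diagnostic ({n} < 200)")
    if np.var(chain) == 0:
        raise ValueError("zero-variance chain")
    seg1 = chain[: int(first * n)]
    seg2 = chain[n - int(last * n):]

    def mean_var(seg: np.ndarray) -> tuple[float, float]:
        m = seg.shape[0]
        nb = max(2, int(round(np.sqrt(m))))
        bs = m // nb
        trimmed = seg[: nb * bs].reshape(nb, bs)
        bm = trimmed.mean(axis=1)
        return float(seg.mean()), float(np.var(bm, ddof=1) / nb)

    m1, v1 = mean_var(seg1)
    m2, v2 = mean_var(seg2)
    if v1 + v2 == 0:
        raise ValueError("zero-variance segments")
    return float((m1 - m2) / np.sqrt(v1 + v2))


def summarize_components(samples: PosteriorSamples) -> ComponentSummary:
    """Posterior-median OR summaries with equal-tailed 95% credible bounds."""
    if samples.n_retained < 100:
        raise ValueError("need at least 100 retained draws to summarize")

    def q(draws, axis=0):
        med = np.median(draws, axis=axis)
        lo, hi = np.quantile(draws, [0.025, 0.975], axis=axis)
        return np.exp(med), np.exp(lo), np.exp(hi)

    sp_or, sp_lo, sp_hi = q(samples.phi)
    te_or, te_lo, te_hi = q(samples.delta)
    unit_table = pd.DataFrame(
        {
            "unit": samples.unit_ids,
            "spatial_or": sp_or,
            "spatial_lo": sp_lo,
            "spatial_hi": sp_hi,
            "spatial_span": sp_hi - sp_lo,
            "temporal_or": te_or,
            "temporal_lo": te_lo,
            "temporal_hi": te_hi,
            "temporal_span": te_hi - te_lo,
        }
    )
    a_or, a_lo, a_hi = q(samples.alpha)
    b_or, b_lo, b_hi = q(samples.beta)
    covariate_table = pd.DataFrame(
        {
            "term": samples.term_names,
            "or": b_or,
            "lo": b_lo,
            "hi": b_hi,
        }
    )
    return ComponentSummary(
        unit_table=unit_table,
        trend_or=float(a_or),
        trend_ci=(float(a_lo), float(a_hi)),
        trend_or_mean=float(np.exp(samples.alpha.mean())),
        covariate_table=covariate_table,
    )


def model3_residuals(panel: ArealPanel, samples: PosteriorSamples) -> np.ndarray:
    """Plug-in empirical-logit residuals under the posterior-median fit.

    eta_hat uses posterior medians of beta, alpha, phi and delta; the
    residual is logit_cc(y, n) - eta_hat, the same continuity-corrected
    scale as the GLM residuals, so Moran's I is comparable across models.
    """
    beta = np.median(samples.beta, axis=0)
    alpha = float(np.median(samples.alpha))
    phi = np.median(samples.phi, axis=0)
    delta = np.median(samples.delta, axis=0)
    t_p = panel.t_p
    eta = np.full((panel.n_units, panel.n_periods), beta[0])
    for j, name in enumerate(samples.term_names[1:], start=1):
        eta = eta + beta[j] * panel.covariates[name]
    eta = eta + phi[:, None] + (alpha + delta[:, None]) * t_p[None, :]
    return logit_residuals(panel, eta)


def prior_sensitivity(
    panel: ArealPanel,
    graph: AdjacencyGraph,
    settings: McmcSettings,
    priors_a: Priors = Priors(),
    priors_b: Priors = ALT_PRIORS,
    covariates: tuple[str, ...] | None = None,
) -> dict:
    """Refit under two prior sets and compare the posterior summaries.

    Returns both ComponentSummary objects plus the absolute difference of
    the national trend log-OR and the max absolute difference of unit-level
    component log-ORs.
    """
    if covariates is None:
        covariates = panel.covariate_names
    res = {}
    for offset, (label, priors) in enumerate(
        (("default", priors_a), ("alternative", priors_b))
    ):
        # distinct seeds so agreement is not an artefact of shared noise
        run_settings = dataclasses.replace(settings, seed=settings.seed + offset)
        samples = run_mcmc(panel, graph, priors=priors, settings=run_settings,
                           covariates=covariates)
        res[label] = summarize_components(samples)
    a, b = res["default"], res["alternative"]
    res["trend_log_or_diff"] = float(abs(np.log(a.trend_or) - np.log(b.trend_or)))
    res["max_unit_log_or_diff"] = float(
        max(
            np.max(np.abs(np.log(a.unit_table["spatial_or"].to_numpy())
                          - np.log(b.unit_table["spatial_or"].to_numpy()))),
            np.max(np.abs(np.log(a.unit_table["temporal_or"].to_numpy())
                          - np.log(b.unit_table["temporal_or"].to_numpy()))),
        )
    )
    return res
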