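"""Maximum-likelihood binomial logistic regression on aggregated panels.

Fits the national-trend models: Model 1 regresses the per-cell death odds
on the centred period index only; Model 2 adds the unit-period covariates.
The fit maximizes the aggregated binomial log-likelihood

    l(beta) = sum_kt [ y_kt eta_kt - n_kt log(1 + exp(eta_kt)) ] + const

by iteratively reweighted least squares with step-halving.  Residuals are
reported on the empirical-logit scale with a 0.5 continuity correction, so
exp(residual) is literally an observed/expected odds ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .panel import ArealPanel

TREND_TERM = "t_p"


class SeparationError(RuntimeError):
    """Raised when the MLE diverges (complete or quasi-complete separation)."""


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, eta)


def _design_matrix(
    panel: ArealPanel, covariates: tuple[str, ...], include_trend: bool = True
) -> tuple[np.ndarray, list[str]]:
    """(K*T) x p design: intercept, centred period index, then covariates."""
    K, T = panel.n_units, panel.n_periods
    cols = [np.ones(K * T)]
    names = ["intercept"]
    if include_trend:
        cols.append(np.tile(panel.t_p, K))
        names.append(TREND_TERM)
    for name in covariates:
        if name not in panel.covariates:
            raise ValueError(f"panel has no covariate {name!r}")
        cols.append(panel.covariates[name].ravel())
        names.append(name)
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[j] for j in np.flatnonzero(diag < tol)]
    if bad:
        raise np.linalg.LinAlgError(f"design matrix rank deficient; collinear columns: {bad}")


class BinomialTrendGLM(BaseEstimator):
    """Binomial logistic regression of areal death counts on a linear trend.

    Parameters
    ----------
    covariates :
        Names of unit-period covariates to include beyond the intercept and
        the centred period index.  Empty tuple gives the trend-only model
        (Model 1); the panel's covariates give the adjusted model (Model 2).
    max_iter, tol_loglik, tol_grad :
        IRLS stopping: relative log-likelihood change below ``tol_loglik`` or
        gradient max-norm below ``tol_grad``.

    Attributes
    ----------
    coef_ : pd.Series
        Fitted coefficients (log-odds scale), indexed by term name.
    cov_ : np.ndarray
        Inverse observed information (Wald covariance).
    eta_ : np.ndarray
        Fitted linear predictors, shape K x T.
    loglik_ : float
    converged_ : bool
    n_iter_ : int
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = (),
        include_trend: bool = True,
        max_iter: int = 100,
        tol_loglik: float = 1e-10,
        tol_grad: float = 1e-8,
    ):
        self.covariates = covariates
        self.include_trend = include_trend
        self.max_iter = max_iter
        self.tol_loglik = tol_loglik
        self.tol_grad = tol_grad

    def fit(self, panel: ArealPanel, y=None) -> "BinomialTrendGLM":
        X, names = _design_matrix(panel, tuple(self.covariates), self.include_trend)
        _check_full_rank(X, names)
        yv = panel.y.ravel().astype(float)
        nv = panel.n.ravel().astype(float)
        if not np.any(yv > 0) or not np.any(yv < nv):
            raise SeparationError("outcome is all-zero or all-trials; MLE does not exist")

        beta = np.zeros(X.shape[1])
        ll = self._loglik(X, yv, nv, beta)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            grad = X.T @ (yv - nv * p)
            w = nv * p * (1.0 - p)
            info = X.T @ (X * w[:, None])
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as err:
                raise SeparationError(f"singular information matrix: {err}") from err
            # step-halving keeps the log-likelihood non-decreasing
            new_ll = -np.inf
            for _ in range(30):
                cand = beta + step
                new_ll = self._loglik(X, yv, nv, cand)
                if new_ll >= ll - 1e-12:
                    break
                step *= 0.5
            beta = beta + step
            if np.max(np.abs(beta)) > 30.0:
                raise SeparationError(
                    "coefficients diverging (|beta| > 30): likely separation"
                )
            rel = abs(new_ll - ll) / (abs(ll) + 1.0)
            ll = new_ll
            grad = X.T @ (yv - nv * (1.0 / (1.0 + np.exp(-(X @ beta)))))
            if rel < self.tol_loglik or np.max(np.abs(grad)) < self.tol_grad:
                converged = True
                break
        if not converged:
            raise SeparationError(f"IRLS failed to converge in {self.max_iter} iterations")

        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = nv * p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        self.term_names_ = names
        self.coef_ = pd.Series(beta, index=names)
        self.cov_ = np.linalg.inv(info)
        self.eta_ = eta.reshape(panel.n_units, panel.n_periods)
        self.loglik_ = float(ll)
        self.converged_ = converged
        self.n_iter_ = it
        return self

    @staticmethod
    def _loglik(X, y, n, beta) -> float:
        eta = X @ beta
        return float(np.sum(y * eta - n * _log1pexp(eta)))

    def predict_proba(self, panel: ArealPanel) -> np.ndarray:
        """Fitted death probabilities for a panel, shape K x T."""
        X, _ = _design_matrix(panel, tuple(self.covariates), self.include_trend)
        eta = X @ self.coef_.to_numpy()
        return (1.0 / (1.0 + np.exp(-eta))).reshape(panel.n_units, panel.n_periods)

    def trend_or(self, z: float = 1.959963984540054) -> tuple[float, float, float]:
        """Per-period trend odds ratio with a 95% Wald interval."""
        if TREND_TERM not in self.coef_.index:
            raise ValueError("fit contains no centred-period term")
        j = list(self.coef_.index).index(TREND_TERM)
        b = self.coef_.iloc[j]
        se = float(np.sqrt(self.cov_[j, j]))
        return float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se))


def fit_logistic(panel: ArealPanel, covariates: tuple[str, ...] = ()) -> BinomialTrendGLM:
    """Fit the trend GLM; empty ``covariates`` is Model 1, the panel's
    sociodemographic columns give Model 2."""
    return BinomialTrendGLM(covariates=covariates).fit(panel)


def empirical_logit(y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """log[(y + 0.5) / (n - y + 0.5)] — continuity-corrected observed log-odds."""
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    return np.log((y + 0.5) / (n - y + 0.5))


def logit_residuals(panel: ArealPanel, eta_hat: np.ndarray) -> np.ndarray:
    """Empirical-logit residuals r_kt = logit_cc(y, n) - eta_hat, shape K x T."""
    return empirical_logit(panel.y, panel.n) - eta_hat


def residual_or(panel: ArealPanel, fit: BinomialTrendGLM) -> pd.DataFrame:
    """Unit-period residual odds ratios exp(r_kt).

    A value above 1 means observed mortality exceeded the model's
    expectation for that unit-period; below 1, fell short of it.
    """
    res = logit_residuals(panel, fit.eta_)
    K, T = panel.n_units, panel.n_periods
    return pd.DataFrame(
        {
            "unit": np.repeat(panel.unit_ids, T),
            "period": np.tile(panel.period_ids, K),
            "residual": res.ravel(),
            "residual_or": np.exp(res).ravel(),
        }
    )


def trend_or(fit: BinomialTrendGLM) -> tuple[float, float, float]:
    """Per-period trend odds ratio and 95% Wald CI from a fitted GLM."""
    return fit.trend_or()
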