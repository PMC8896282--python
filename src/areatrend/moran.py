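"""Global Moran's I and its Monte-Carlo permutation test.

Moran's I measures global spatial autocorrelation of a vector x over the
areal units:

    I = (K / S0) * sum_{k,j} w_kj (x_k - xbar)(x_j - xbar) / sum_k (x_k - xbar)^2

with S0 = sum_{k,j} w_kj over ordered pairs (S0 = 2 |edges| for the binary
symmetric weights used here).  Values above the null expectation -1/(K-1)
indicate neighbours are more alike than chance.  Significance is assessed by
uniformly permuting x over the units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import AdjacencyGraph


@dataclass(frozen=True)
class MoranResult:
    I: float
    p_value: float
    n_perm: int
    expected_I: float
    alternative: str = "greater"

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Significance codes: * P<0.05, ** P<0.01, *** P<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _moran_num_den(z: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # z: (..., K) centred values; returns numerator sum w_kj z_k z_j and sum z^2
    num = ((z @ W) * z).sum(axis=-1)
    den = (z * z).sum(axis=-1)
    return num, den


def morans_i(
    x: np.ndarray,
    graph: AdjacencyGraph,
    row_standardized: bool = False,
) -> float:
    """Global Moran's I of x over the graph's units.

    Binary weights by default, matching a binary border-adjacency matrix;
    ``row_standardized=True`` divides each row of W by its degree.
    """
    x = np.asarray(x, dtype=float)
    K = graph.n_units
    if x.shape != (K,):
        raise ValueError(f"x has shape {x.shape}, expected ({K},)")
    if K < 3:
        raise ValueError("Moran's I requires at least 3 units")
    z = x - x.mean()
    if np.allclose(z, 0.0):
        raise ValueError("Moran's I undefined for a constant vector")
    W = graph.W
    if row_standardized:
        W = W / W.sum(axis=1, keepdims=True)
    S0 = W.sum()
    num, den = _moran_num_den(z, W)
    return float((K / S0) * num / den)


def moran_permutation_test(
    x: np.ndarray,
    graph: AdjacencyGraph,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    alternative: str = "greater",
    row_standardized: bool = False,
) -> MoranResult:
    """Monte-Carlo permutation test for Moran's I.

    The observed statistic is compared with ``n_perm`` uniform relabelings
    of x over the units; the one-sided (greater) p-value is
    (1 + #{I_perm >= I_obs}) / (1 + n_perm), so the smallest attainable
    p is 1/(n_perm + 1).  Deterministic given the seed.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = np.asarray(x, dtype=float)
    K = graph.n_units
    obs = morans_i(x, graph, row_standardized=row_standardized)

    W = graph.W
    if row_standardized:
        W = W / W.sum(axis=1, keepdims=True)
    S0 = W.sum()
    z = x - x.mean()
    perms = rng.permuted(np.broadcast_to(z, (n_perm, K)), axis=1)
    num, den = _moran_num_den(perms, W)
    I_perm = (K / S0) * num / den

    exp_I = -1.0 / (K - 1)
    if alternative == "greater":
        extreme = np.count_nonzero(I_perm >= obs)
    elif alternative == "less":
        extreme = np.count_nonzero(I_perm <= obs)
    else:
        extreme = np.count_nonzero(np.abs(I_perm - exp_I) >= abs(obs - exp_I))
    p = (1.0 + extreme) / (1.0 + n_perm)
    return MoranResult(I=obs, p_value=float(p), n_perm=n_perm, expected_I=exp_I,
                       alternative=alternative)


def moran_table(
    residuals: dict[str, np.ndarray],
    graph: AdjacencyGraph,
    period_ids: tuple[str, ...],
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-model, per-period Moran's I report with significance stars.

    ``residuals`` maps a model label to a K x T residual matrix.  Output has
    one row per model x period: statistic, Monte-Carlo p-value and stars.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for model, res in residuals.items():
        for j, period in enumerate(period_ids):
            result = moran_permutation_test(res[:, j], graph, n_perm=n_perm, seed=rng)
            rows.append(
                {
                    "model": model,
                    "period": period,
                    "moran_i": result.I,
                    "p_value": result.p_value,
                    "stars": result.stars,
                }
            )
    return pd.DataFrame(rows)
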