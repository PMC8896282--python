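"""Areal binomial panels and adjacency structures.

The basic data objects of small-area disease mapping: a unit x period panel
of event counts (deaths within 28 days of an incident AMI) and trial counts
(incident AMIs), with unit-period covariates, and an undirected binary
neighbourhood graph over the areal units (municipalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: Default covariate columns: mean age at AMI plus the four sociodemographic
#: municipality-level proportions.
DEFAULT_COVARIATES: tuple[str, ...] = (
    "ami_age",
    "cohabitation",
    "low_education",
    "unemployment",
    "low_income",
)

PANEL_COLUMNS = ("unit", "period", "cases", "deaths")


class PanelValidationError(ValueError):
    """Raised when a panel or adjacency structure violates an invariant."""


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected binary neighbourhood structure over areal units.

    Parameters
    ----------
    unit_ids :
        Ordered unit labels (length K). Row/column order of ``W``.
    edges :
        Set of unordered label pairs, stored as sorted 2-tuples.
    """

    unit_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {u: i for i, u in enumerate(self.unit_ids)}
        if len(index) != len(self.unit_ids):
            raise PanelValidationError("duplicate unit labels in adjacency graph")
        object.__setattr__(self, "_index", index)
        for a, b in self.edges:
            if a == b:
                raise PanelValidationError(f"self-loop on unit {a!r}")
            for u in (a, b):
                if u not in index:
                    raise PanelValidationError(f"edge references unknown unit {u!r}")
        deg = self.degrees
        if np.any(deg == 0):
            isolated = [u for u, d in zip(self.unit_ids, deg) if d == 0]
            raise PanelValidationError(f"isolated units (degree 0): {isolated}")
        if self.n_components > 1:
            warnings.warn(
                f"adjacency graph has {self.n_components} connected components",
                stacklevel=2,
            )

    @classmethod
    def from_edges(
        cls, unit_ids: list[str] | tuple[str, ...], edges
    ) -> "AdjacencyGraph":
        norm = frozenset(tuple(sorted((str(a), str(b)))) for a, b in edges)
        return cls(tuple(str(u) for u in unit_ids), norm)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def index_of(self, unit: str) -> int:
        return self._index[unit]

    @property
    def W(self) -> np.ndarray:
        """K x K binary symmetric adjacency matrix with zero diagonal."""
        K = self.n_units
        W = np.zeros((K, K))
        for a, b in self.edges:
            i, j = self._index[a], self._index[b]
            W[i, j] = W[j, i] = 1.0
        return W

    @property
    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_units)
        for a, b in self.edges:
            d[self._index[a]] += 1
            d[self._index[b]] += 1
        return d

    @property
    def n_components(self) -> int:
        g = self.to_networkx()
        return nx.number_connected_components(g)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.unit_ids)
        g.add_edges_from(self.edges)
        return g

    def neighbour_lists(self) -> list[np.ndarray]:
        """Neighbour index arrays, one per unit (fitting-code convenience)."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_units)]
        for a, b in self.edges:
            i, j = self._index[a], self._index[b]
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.array(sorted(v), dtype=np.intp) for v in nbrs]


@dataclass(frozen=True)
class ArealPanel:
    """Unit x period binomial panel.

    ``y`` (events) and ``n`` (trials) are K x T integer arrays; covariates is
    a mapping from covariate name to a K x T float array.  ``t_p`` is the
    centred period index t_p = p - (T+1)/2 for period rank p in 1..T, so one
    unit of t is one period and sum(t_p) = 0.
    """

    unit_ids: tuple[str, ...]
    period_ids: tuple[str, ...]
    y: np.ndarray
    n: np.ndarray
    covariates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        K, T = len(self.unit_ids), len(self.period_ids)
        for name, arr in (("y", self.y), ("n", self.n)):
            if arr.shape != (K, T):
                raise PanelValidationError(f"{name} has shape {arr.shape}, expected {(K, T)}")
        if np.any(self.y < 0) or np.any(self.n < 0):
            raise PanelValidationError("negative counts")
        bad = np.argwhere(self.y > self.n)
        if bad.size:
            k, t = bad[0]
            raise PanelValidationError(
                f"deaths exceed cases for unit {self.unit_ids[k]!r}, "
                f"period {self.period_ids[t]!r} ({self.y[k, t]} > {self.n[k, t]})"
            )
        for name, arr in self.covariates.items():
            if arr.shape != (K, T):
                raise PanelValidationError(
                    f"covariate {name!r} has shape {arr.shape}, expected {(K, T)}"
                )

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_periods(self) -> int:
        return len(self.period_ids)

    @property
    def t_p(self) -> np.ndarray:
        """Centred period index: p - (T+1)/2 for p = 1..T."""
        T = self.n_periods
        return np.arange(1, T + 1, dtype=float) - (T + 1) / 2.0

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.covariates)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame, one row per unit-period."""
        K, T = self.n_units, self.n_periods
        rows = {
            "unit": np.repeat(self.unit_ids, T),
            "period": np.tile(self.period_ids, K),
            "cases": self.n.ravel(),
            "deaths": self.y.ravel(),
        }
        for name, arr in self.covariates.items():
            rows[name] = arr.ravel()
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        covariates: tuple[str, ...] | None = None,
        period_order: list[str] | None = None,
    ) -> "ArealPanel":
        """Build a validated panel from a long-format DataFrame.

        Every unit x period cell must be present exactly once; counts must be
        non-negative integers with deaths <= cases.
        """
        for col in PANEL_COLUMNS:
            if col not in df.columns:
                raise PanelValidationError(f"missing required column {col!r}")
        if covariates is None:
            covariates = tuple(c for c in DEFAULT_COVARIATES if c in df.columns)
        df = df.copy()
        df["unit"] = df["unit"].astype(str)
        df["period"] = df["period"].astype(str)
        unit_ids = tuple(sorted(df["unit"].unique()))
        if period_order is not None:
            period_ids = tuple(str(p) for p in period_order)
            unknown = set(df["period"]) - set(period_ids)
            if unknown:
                raise PanelValidationError(f"periods not in period_order: {sorted(unknown)}")
        else:
            period_ids = tuple(sorted(df["period"].unique()))

        for col in ("cases", "deaths"):
            vals = df[col].to_numpy()
            rounded = np.rint(np.asarray(vals, dtype=float))
            if not np.allclose(vals, rounded, atol=1e-9):
                raise PanelValidationError(f"non-integer values in column {col!r}")
            df[col] = rounded.astype(np.int64)

        dup = df.duplicated(subset=["unit", "period"])
        if dup.any():
            row = df[dup].iloc[0]
            raise PanelValidationError(
                f"duplicate cell for unit {row['unit']!r}, period {row['period']!r}"
            )

        K, T = len(unit_ids), len(period_ids)
        uidx = {u: i for i, u in enumerate(unit_ids)}
        pidx = {p: j for j, p in enumerate(period_ids)}
        y = np.full((K, T), -1, dtype=np.int64)
        n = np.full((K, T), -1, dtype=np.int64)
        cov = {name: np.full((K, T), np.nan) for name in covariates}
        for _, row in df.iterrows():
            i, j = uidx[row["unit"]], pidx[row["period"]]
            y[i, j] = row["deaths"]
            n[i, j] = row["cases"]
            for name in covariates:
                cov[name][i, j] = row[name]
        missing = np.argwhere(n < 0)
        if missing.size:
            k, t = missing[0]
            raise PanelValidationError(
                f"missing cell for unit {unit_ids[k]!r}, period {period_ids[t]!r}"
            )
        return cls(unit_ids, period_ids, y, n, cov)


def read_panel(
    path,
    covariates: tuple[str, ...] | None = None,
    period_order: list[str] | None = None,
) -> ArealPanel:
    """Read a unit x period panel from CSV.

    Expected columns: ``unit, period, cases, deaths`` plus covariate columns.
    """
    df = pd.read_csv(path)
    return ArealPanel.from_frame(df, covariates=covariates, period_order=period_order)


def write_panel(panel: ArealPanel, path) -> None:
    panel.to_frame().to_csv(path, index=False)


def read_adjacency(path, unit_ids: list[str] | tuple[str, ...]) -> AdjacencyGraph:
    """Read a neighbourhood structure as an edge list or a GAL file.

    Edge-list dialect: two whitespace- or comma-separated unit labels per
    line (``#`` comments allowed).  GAL dialect: a header line whose first
    (or only numeric) token is the unit count, then per unit a
    ``label n_neighbours`` line followed by a line of neighbour labels.
    Duplicate edges are collapsed; edges must connect known units.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise PanelValidationError(f"empty adjacency file: {path}")

    edges: set[tuple[str, str]] = set()
    header = lines[0].replace(",", " ").split()
    is_gal = all(_is_int(tok) for tok in header) and (
        len(header) in (1, 4) or (len(header) == 2 and _is_int(header[0]))
    )
    known = {str(u) for u in unit_ids}

    def add_edge(a: str, b: str) -> None:
        if a == b:
            raise PanelValidationError(f"self-loop on unit {a!r}")
        for u in (a, b):
            if u not in known:
                raise PanelValidationError(f"adjacency references unknown unit {u!r}")
        edges.add(tuple(sorted((a, b))))

    if is_gal:
        # GAL: header then (node line, neighbour line) pairs
        i = 1
        while i < len(lines):
            node_tokens = lines[i].replace(",", " ").split()
            if len(node_tokens) < 2:
                raise PanelValidationError(f"malformed GAL node line: {lines[i]!r}")
            label, count = node_tokens[0], int(node_tokens[-1])
            i += 1
            if count == 0:
                continue
            if i >= len(lines):
                raise PanelValidationError(f"GAL file truncated after node {label!r}")
            nbrs = lines[i].replace(",", " ").split()
            if len(nbrs) != count:
                raise PanelValidationError(
                    f"GAL node {label!r} declares {count} neighbours, found {len(nbrs)}"
                )
            for b in nbrs:
                add_edge(label, b)
            i += 1
    else:
        for ln in lines:
            tokens = ln.replace(",", " ").split()
            if len(tokens) != 2:
                raise PanelValidationError(f"malformed edge line: {ln!r}")
            add_edge(*tokens)

    return AdjacencyGraph.from_edges(tuple(str(u) for u in unit_ids), edges)


def _is_int(tok: str) -> bool:
    try:
        int(tok)
    except ValueError:
        return False
    return True


def standardize_covariates(panel: ArealPanel) -> ArealPanel:
    """Standardize each covariate within each period across units.

    Subtracts the across-unit mean and divides by the sample standard
    deviation (K-1 denominator), separately in every period, so that each
    covariate reflects between-unit contrasts rather than national temporal
    trends.  Counts are untouched.  Idempotent to floating-point tolerance.
    """
    if panel.n_units < 2:
        raise PanelValidationError("standardization requires at least 2 units per period")
    out: dict[str, np.ndarray] = {}
    for name, arr in panel.covariates.items():
        mu = arr.mean(axis=0, keepdims=True)
        sd = arr.std(axis=0, ddof=1, keepdims=True)
        zero = np.flatnonzero(sd.ravel() == 0)
        if zero.size:
            raise PanelValidationError(
                f"covariate {name!r} has zero variance in period "
                f"{panel.period_ids[zero[0]]!r}"
            )
        out[name] = (arr - mu) / sd
    return ArealPanel(panel.unit_ids, panel.period_ids, panel.y, panel.n, out)


def period_summaries(panel: ArealPanel) -> pd.DataFrame:
    """Per-period national totals and mortality percentages.

    One row per period with total trials, total events and the mortality
    percentage 100 * events / trials rounded to one decimal, plus a grand
    ``total`` row.  Totals use exact integer arithmetic.
    """
    cases = panel.n.sum(axis=0)
    deaths = panel.y.sum(axis=0)
    rows = pd.DataFrame(
        {
            "period": list(panel.period_ids) + ["total"],
            "cases": np.append(cases, cases.sum()),
            "deaths": np.append(deaths, deaths.sum()),
        }
    )
    rows["mortality_pct"] = (100.0 * rows["deaths"] / rows["cases"]).round(1)
    return rows
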