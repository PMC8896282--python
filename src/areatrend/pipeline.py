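"""Full study workflow: panel -> Models 1/2/3 -> Moran tables -> outputs.

Orchestrates the analysis sequence the package exists for: load (or
simulate) a unit x period binomial panel and its adjacency graph, fit the
trend-only GLM (Model 1), the sociodemographics-adjusted GLM (Model 2) and
the Leroux-CAR spatio-temporal model (Model 3), compute per-period Moran's
I permutation tests on each model's empirical-logit residuals, and write
tabular outputs mirroring the study's tables and maps:

- period_summaries.csv   : per-period national totals and mortality %
- mortality_relative.csv : unit proportions vs the across-unit period mean
- residual_or_model2.csv : Model 2 residual ORs per unit-period
- component_summary.csv  : Model 3 spatial/temporal component ORs + CIs
- moran_table.csv        : Moran's I with significance stars, model x period
- diagnostics.csv        : Geweke Z and acceptance rates for Model 3
- manifest.json          : seed, settings, input hashes — enough to replay
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import car, glm, moran, panel as panel_mod, simulate
from .panel import AdjacencyGraph, ArealPanel


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    Either ``panel_path`` + ``adjacency_path`` (real data) or ``scenario``
    (synthetic) must be given.  The seed is mandatory: every stochastic
    stage (simulation, permutations, MCMC) derives its stream from it.
    """

    out_dir: str
    seed: int
    panel_path: str | None = None
    adjacency_path: str | None = None
    geojson_path: str | None = None
    scenario: simulate.SimulationScenario | None = None
    models: tuple[int, ...] = (1, 2, 3)
    n_perm: int = 9999
    mcmc: car.McmcSettings | None = None
    priors: car.Priors = car.Priors()
    standardize: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "scenario" in raw and raw["scenario"] is not None:
            raw["scenario"] = simulate.SimulationScenario(**raw["scenario"])
        if "mcmc" in raw and raw["mcmc"] is not None:
            raw["mcmc"] = car.McmcSettings(**raw["mcmc"])
        if "priors" in raw and raw["priors"] is not None:
            raw["priors"] = car.Priors(**raw["priors"])
        if "models" in raw:
            raw["models"] = tuple(int(m) for m in raw["models"])
        return cls(**raw)


def national_relative_mortality(panel: ArealPanel) -> pd.DataFrame:
    """Unit-period mortality proportions relative to the period mean.

    For every period the reference is the *unweighted* mean of the unit
    proportions (each municipality counts once, regardless of size); the
    ``relative`` column is the unit's proportion minus that mean, the
    quantity behind the red/white/green unadjusted-mortality maps.  Cells
    with zero trials are excluded with a warning.
    """
    rows = []
    for j, period in enumerate(panel.period_ids):
        n = panel.n[:, j].astype(float)
        y = panel.y[:, j].astype(float)
        ok = n > 0
        if not ok.all():
            excl = [panel.unit_ids[i] for i in np.flatnonzero(~ok)]
            warnings.warn(f"period {period!r}: excluding zero-trial units {excl}",
                          stacklevel=2)
        prop = np.full(n.shape, np.nan)
        prop[ok] = y[ok] / n[ok]
        mean = prop[ok].mean()
        for i in np.flatnonzero(ok):
            rows.append(
                {
                    "unit": panel.unit_ids[i],
                    "period": period,
                    "proportion": prop[i],
                    "period_mean": mean,
                    "relative": prop[i] - mean,
                }
            )
    return pd.DataFrame(rows)


def join_geojson(table: pd.DataFrame, geojson_path, out_path, unit_property: str = "unit") -> None:
    """Pass-through join of a unit-keyed table onto GeoJSON feature properties."""
    with open(geojson_path, encoding="utf-8") as fh:
        gj = json.load(fh)
    by_unit = {str(r["unit"]): {k: v for k, v in r.items() if k != "unit"}
               for r in table.to_dict("records")}
    for feat in gj.get("features", []):
        label = str(feat.get("properties", {}).get(unit_property, ""))
        if label in by_unit:
            feat.setdefault("properties", {}).update(by_unit[label])
    with open(out_path, "w", encoding="utf-8") as fh:
        json.dump(gj, fh)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_study(config: RunConfig) -> dict:
    """Execute the full workflow and write every output table.

    Returns a dict with the in-memory results (panel, fits, tables,
    manifest).  Re-running with the same config and seed reproduces every
    output file byte-for-byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "models": list(config.models),
        "n_perm": config.n_perm,
        "stages_completed": [],
        "inputs": {},
    }

    # --- stage: inputs ------------------------------------------------------
    try:
        if config.scenario is not None:
            scenario = dataclasses.replace(config.scenario, seed=config.seed)
            pnl, truth = simulate.simulate_panel(scenario)
            graph = simulate.make_graph(scenario)
            with open(out / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(truth, fh, indent=1)
            manifest["inputs"]["scenario"] = dataclasses.asdict(scenario)
        elif config.panel_path and config.adjacency_path:
            pnl = panel_mod.read_panel(config.panel_path)
            graph = panel_mod.read_adjacency(config.adjacency_path, pnl.unit_ids)
            manifest["inputs"] = {
                "panel": {"path": str(config.panel_path), "sha256": _sha256(config.panel_path)},
                "adjacency": {"path": str(config.adjacency_path),
                              "sha256": _sha256(config.adjacency_path)},
            }
        else:
            raise ValueError("config needs either a scenario or panel+adjacency paths")
        if config.standardize and config.scenario is None:
            pnl = panel_mod.standardize_covariates(pnl)
    except Exception as err:
        _write_manifest(out, manifest)
        raise RuntimeError(f"stage 'inputs' failed: {err}") from err
    manifest["stages_completed"].append("inputs")

    results: dict = {"panel": pnl, "graph": graph}
    residuals: dict[str, np.ndarray] = {}

    # --- stage: descriptives ------------------------------------------------
    panel_mod.period_summaries(pnl).to_csv(out / "period_summaries.csv", index=False)
    national_relative_mortality(pnl).to_csv(out / "mortality_relative.csv", index=False)
    manifest["stages_completed"].append("descriptives")

    # --- stage: GLMs --------------------------------------------------------
    try:
        if 1 in config.models:
            fit1 = glm.fit_logistic(pnl, covariates=())
            residuals["Model 1"] = glm.logit_residuals(pnl, fit1.eta_)
            results["model1"] = fit1
        if 2 in config.models:
            fit2 = glm.fit_logistic(pnl, covariates=pnl.covariate_names)
            residuals["Model 2"] = glm.logit_residuals(pnl, fit2.eta_)
            results["model2"] = fit2
            glm.residual_or(pnl, fit2).to_csv(out / "residual_or_model2.csv", index=False)
    except Exception as err:
        _write_manifest(out, manifest)
        raise RuntimeError(f"stage 'glm' failed: {err}") from err
    manifest["stages_completed"].append("glm")

    # --- stage: CAR model ---------------------------------------------------
    if 3 in config.models:
        try:
            settings = config.mcmc or car.McmcSettings(seed=config.seed)
            settings = dataclasses.replace(settings, seed=config.seed)
            samples = car.run_mcmc(pnl, graph, priors=config.priors, settings=settings)
            summary = car.summarize_components(samples)
            residuals["Model 3"] = car.model3_residuals(pnl, samples)
            results["model3"] = samples
            results["summary"] = summary
            tab = summary.unit_table.copy()
            tab.to_csv(out / "component_summary.csv", index=False)
            diag = pd.DataFrame(
                [
                    {
                        "parameter": name,
                        "geweke_z": car.geweke_diagnostic(chain)
                        if np.var(chain) > 0 else np.nan,
                        "acceptance_rate": samples.acceptance.get(acc_key, np.nan),
                    }
                    for name, chain, acc_key in (
                        ("alpha", samples.alpha, "alpha"),
                        ("intercept", samples.beta[:, 0], "beta"),
                        ("tau2_phi", samples.tau2_phi, ""),
                        ("tau2_delta", samples.tau2_delta, ""),
                        ("rho_phi", samples.rho_phi, "rho_phi"),
                        ("rho_delta", samples.rho_delta, "rho_delta"),
                        ("log_posterior", samples.log_post, ""),
                    )
                ]
            )
            diag.to_csv(out / "diagnostics.csv", index=False)
            manifest["trend_or"] = summary.trend_or
            manifest["trend_ci"] = list(summary.trend_ci)
            manifest["mcmc"] = dataclasses.asdict(settings)
            if config.geojson_path:
                join_geojson(tab, config.geojson_path, out / "components.geojson")
        except Exception as err:
            _write_manifest(out, manifest)
            raise RuntimeError(f"stage 'car' failed: {err}") from err
        manifest["stages_completed"].append("car")

    # --- stage: Moran -------------------------------------------------------
    if residuals:
        try:
            table = moran.moran_table(
                residuals, graph, pnl.period_ids, n_perm=config.n_perm,
                seed=config.seed,
            )
            table.to_csv(out / "moran_table.csv", index=False)
            results["moran_table"] = table
        except Exception as err:
            _write_manifest(out, manifest)
            raise RuntimeError(f"stage 'moran' failed: {err}") from err
        manifest["stages_completed"].append("moran")

    manifest["complete"] = True
    _write_manifest(out, manifest)
    results["manifest"] = manifest
    return results


def _write_manifest(out: Path, manifest: dict) -> None:
    manifest.setdefault("complete", False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
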