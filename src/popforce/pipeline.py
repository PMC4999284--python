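"""Configuration and the end-to-end pipeline.

One :class:`RunConfig` drives the whole analysis: obtain inputs (from CSV
/ RWL files, or from the synthetic generator when no paths are given),
optionally build the rainfall-proxy chronology from raw ring widths,
assemble growth records on the decade grid, fit and rank the candidate
models, forward-simulate the best model from the first census value, and
write a report (CSV tables plus a JSON summary).  Everything is
deterministic given the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import chronology as chron_mod
from . import io as pio
from .demography import growth_records, records_to_frame
from .fitting import fit_models, selection_table
from .models import get_spec
from .series import AnnualSeries, PopulationSeries
from .simulate import TrajectoryDiverged, prediction_correlation, simulate_trajectory
from .synthetic import ScenarioConfig, generate_bundle

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a run needs; loadable from YAML via :meth:`from_yaml`."""

    period: tuple[int, int] = (1820, 1960)
    decade_step: int = 10
    models: tuple = ("1", "2", "3", "4", "5", "6")
    bic_n: str = "n_records+1"
    gdp_agg: str = "mean"
    n_starts: int = 50
    seed: int = 1
    correlation_scale: str = "log"
    eps_window: int = 30
    eps_overlap: int = 15
    population_csv: str | None = None
    gdp_csv: str | None = None
    rain_csv: str | None = None
    rwl: str | None = None
    synthetic: dict = field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        start, end = self.period
        if start >= end:
            raise ValueError("period start must precede end")
        if (end - start) % self.decade_step != 0:
            raise ValueError("decade_step must divide the period")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "period" in data:
            data["period"] = tuple(data["period"])
        if "models" in data:
            data["models"] = tuple(str(m) for m in data["models"])
        return cls(**data)


def _load_inputs(cfg: RunConfig):
    """Resolve population/gdp/rain inputs from paths or the generator."""
    chronology = None
    if cfg.population_csv:
        pop = pio.read_series_csv(cfg.population_csv, kind="population")
        gdp = pio.read_series_csv(cfg.gdp_csv, kind="annual") if cfg.gdp_csv else None
        rain = pio.read_series_csv(cfg.rain_csv, kind="annual") if cfg.rain_csv else None
    else:
        scenario = ScenarioConfig(**{"seed": cfg.seed, **cfg.synthetic})
        bundle = generate_bundle(scenario)
        pop, gdp, rain = bundle["population"], bundle["gdp"], bundle["rain"]
    if cfg.rwl:
        rings = pio.read_rwl(cfg.rwl)
        detrended = chron_mod.detrend_set(rings)
        chronology = chron_mod.build_chronology(
            detrended, window=cfg.eps_window, overlap=cfg.eps_overlap)
        rain = chronology.as_series(name="rain")
    return pop, gdp, rain, chronology


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute chronology -> records -> fits -> selection -> simulation.

    Returns the report dict; when ``cfg.out_dir`` is set the tables and a
    ``summary.json`` are also written there.
    """
    try:
        pop, gdp, rain, chronology = _load_inputs(cfg)
    except Exception as exc:
        raise PipelineError("inputs", str(exc)) from exc

    try:
        pop_period = pop.restrict(*cfg.period)
        records = growth_records(pop_period, gdp, rain, gdp_agg=cfg.gdp_agg)
        log.info("built %d growth records over %s", len(records), cfg.period)
    except Exception as exc:
        raise PipelineError("records", str(exc)) from exc

    try:
        fits = fit_models(records, model_ids=cfg.models, n_starts=cfg.n_starts,
                          seed=cfg.seed, bic_n=cfg.bic_n)
        table = selection_table(fits)
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    best = fits[table.best_id]
    try:
        g_path = np.array([r.gdp for r in records])
        w_path = np.array([r.rain for r in records])
        years = np.append([r.year for r in records],
                          records[-1].year + cfg.decade_step)
        traj = simulate_trajectory(get_spec(best.spec_id), best.params,
                                   float(pop_period.log_counts[0]), years,
                                   g_path, w_path)
        pred_r = prediction_correlation(pop_period, traj,
                                        scale=cfg.correlation_scale)
        traj_years = traj.years.tolist()
        traj_n = traj.N.tolist()
    except TrajectoryDiverged as exc:
        log.warning("best-model trajectory diverged: %s", exc)
        pred_r, traj_years, traj_n = None, exc.partial.years.tolist(), exc.partial.N.tolist()
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    report = {
        "period": list(cfg.period),
        "n_records": len(records),
        "best_id": table.best_id,
        "best_params": best.params.as_dict(get_spec(best.spec_id)),
        "prediction_r": pred_r,
        "selection": table.rows.to_dict(orient="records"),
        "chronology_rbar": chronology.rbar if chronology else None,
        "seed": cfg.seed,
    }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_to_frame(records).to_csv(out / "records.csv", index=False)
        table.rows.to_csv(out / "selection.csv", index=False)
        import pandas as pd

        pd.DataFrame({"year": traj_years, "N_pred": traj_n}).to_csv(
            out / "trajectory.csv", index=False)
        with open(out / "params.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump({mid: f.to_dict() for mid, f in fits.items()}, fh,
                           sort_keys=True)
        if chronology is not None:
            chronology.to_frame().to_csv(out / "chronology.csv", index=False)
            chron_mod.eps_table(chronology.eps_windows).to_csv(
                out / "eps.csv", index=False)
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
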