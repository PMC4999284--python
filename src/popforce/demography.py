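"""From census counts and annual covariates to model-ready growth records.

The realized per-capita growth rate over one census interval of length d
years is R_t = ln N_t - ln N_{t-d}.  Each record pairs the rate realized
over [t, t+d) with the log population X_t at the interval start and with
decadal covariate aggregates (arithmetic means of the annual values over
the half-open interval [t, t+d)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import AnnualSeries, PopulationSeries, SeriesError

__all__ = ["GrowthRecord", "realized_growth_rate", "growth_records", "records_to_frame"]

log = logging.getLogger(__name__)


class InsufficientDataError(SeriesError):
    """Fewer usable growth records than the analysis can support."""


@dataclass(frozen=True)
class GrowthRecord:
    """One aligned regression row: (X_t, R over [t, t+d), covariates at t)."""

    year: int
    X: float          # ln persons at interval start
    R_next: float     # per-capita growth over the interval (per decade)
    gdp: float        # decadal GDP aggregate (dollars)
    rain: float       # decadal mean rainfall-proxy index


def realized_growth_rate(n_t: float, n_prev: float) -> float:
    """R = ln(n_t) - ln(n_prev); both counts must be positive."""
    if n_t <= 0 or n_prev <= 0:
        raise ValueError("population counts must be positive to form ln ratios")
    return math.log(n_t) - math.log(n_prev)


def growth_records(
    pop: PopulationSeries,
    gdp: AnnualSeries | None = None,
    rain: AnnualSeries | None = None,
    period: tuple[int, int] | None = None,
    gdp_agg: str = "mean",
    min_records: int = 3,
) -> list[GrowthRecord]:
    """Build one record per consecutive census pair.

    Covariates are aggregated over the interval [year_t, year_t + d - 1]:
    the rain index as a decadal mean, GDP as a decadal mean by default
    (``gdp_agg="start_year"`` takes the interval's first annual value
    instead).  A missing series contributes its neutral element (GDP 0,
    rain 1) so forcing-free models run without covariates.  Records whose
    covariate window has gaps are dropped with a logged warning.
    """
    if gdp_agg not in ("mean", "start_year"):
        raise ValueError("gdp_agg must be 'mean' or 'start_year'")
    if period is not None:
        pop = pop.restrict(*period)
    if len(pop) < 2:
        raise InsufficientDataError("need at least two census points")
    step = pop.step
    X = pop.log_counts
    records: list[GrowthRecord] = []
    dropped: list[int] = []
    for i in range(len(pop) - 1):
        year = int(pop.years[i])
        r_next = float(X[i + 1] - X[i])
        try:
            if gdp is None:
                g = 0.0
            elif gdp_agg == "mean":
                g = gdp.mean_over(year, step)
            else:
                g = gdp.value_at(year)
            w = 1.0 if rain is None else rain.mean_over(year, step)
        except (SeriesError, KeyError):
            dropped.append(year)
            continue
        records.append(GrowthRecord(year=year, X=float(X[i]), R_next=r_next, gdp=g, rain=w))
    if dropped:
        log.warning("dropped %d record(s) with incomplete covariates: %s", len(dropped), dropped)
    if len(records) < min_records:
        raise InsufficientDataError(
            f"only {len(records)} usable record(s); need at least {min_records}")
    return records


def records_to_frame(records: list[GrowthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [r.year for r in records],
            "X": [r.X for r in records],
            "R_next": [r.R_next for r in records],
            "gdp": [r.gdp for r in records],
            "rain": [r.rain for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[GrowthRecord]:
    needed = {"year", "X", "R_next", "gdp", "rain"}
    if not needed.issubset(df.columns):
        raise SeriesError(f"records table must have columns {sorted(needed)}")
    return [
        GrowthRecord(int(r.year), float(r.X), float(r.R_next), float(r.gdp), float(r.rain))
        for r in df.itertuples()
    ]


def record_arrays(records) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(X, R_next, gdp, rain) as aligned arrays."""
    X = np.array([r.X for r in records])
    R = np.array([r.R_next for r in records])
    g = np.array([r.gdp for r in records])
    w = np.array([r.rain for r in records])
    return X, R, g, w
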