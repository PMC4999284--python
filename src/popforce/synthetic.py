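"""Synthetic data with the statistical structure of the study system.

Every input of the analysis can be generated here so the full pipeline is
testable without external data:

* a GDP-like covariate: geometric growth (log random walk with drift),
  emulating a national per-capita GDP series in constant dollars;
* a rainfall proxy: AR(1) deviations around a linearly trending mean,
  emulating a ring-width index with a wet early phase and a persistent
  decline;
* multi-tree ring-width series: per-tree negative-exponential age curves
  modulated by a shared climate signal under multiplicative lognormal
  noise, for exercising the chronology pipeline;
* a census series: forward iteration of a chosen R-function model with
  additive Gaussian process noise on R (so ln N stays Gaussian and N
  stays positive), emulating a growth phase followed by sustained
  decline under rising GDP and falling rainfall.

All generators draw from sub-streams split deterministically off one
scenario seed, so a scenario reproduces bit-for-bit.

The default :class:`ScenarioConfig` encodes the study conditions: fifteen
decadal census points over 1820-1960, the ratio-forced Ricker variant
(catalogue model 6) with its published parameters, process noise of 0.05
on R, GDP growing from 700 dollars at 1.4 %/yr, and a rain index easing
from ~1.2 with a secular decline of 0.0025/yr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import CATALOG_PARAMS, ModelError, ParamVector, get_spec, predict_r
from .series import AnnualSeries, PopulationSeries, SeriesError, TreeRingSet

__all__ = [
    "ScenarioConfig",
    "gen_gdp",
    "gen_rainfall_proxy",
    "gen_tree_ring_set",
    "gen_population",
    "generate_bundle",
]

#: per-tree age-curve parameter ranges: amplitude a (mm), decay b (1/yr),
#: asymptote k (mm) of  width = a*exp(-b*age) + k
DEFAULT_AGE_CURVE = {"a": (0.8, 1.6), "b": (0.01, 0.05), "k": (0.2, 0.6)}


@dataclass
class ScenarioConfig:
    """One reproducible synthetic study: census + covariates + noise levels."""

    start_year: int = 1820
    n_decades: int = 15          # census points, decade-spaced
    initial_pop: float = 1500.0  # persons at start_year
    model: str = "6"
    params: ParamVector | None = None   # None -> catalogue estimate for `model`
    process_sd: float = 0.05     # sd of additive noise on R, per decade
    gdp_start: float = 700.0     # dollars at start_year
    gdp_growth: float = 0.014    # per-year log growth rate
    gdp_noise_sd: float = 0.03   # sd of log-GDP innovations
    rain_mean: float = 1.2       # index level at start_year
    rain_ar1: float = 0.3
    rain_trend: float = -0.0025  # index units per year
    rain_sd: float = 0.08        # AR(1) innovation sd
    rain_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_pop <= 0:
            raise ValueError("initial_pop must be > 0")
        if self.n_decades < 3:
            raise ValueError("need at least 3 decades")
        if not 0 <= self.rain_ar1 < 1:
            raise ValueError("rain_ar1 must lie in [0, 1)")
        if self.process_sd < 0:
            raise ValueError("process_sd must be >= 0")
        if self.params is None:
            self.params = CATALOG_PARAMS[str(self.model)]

    @property
    def n_years(self) -> int:
        """Annual covariate span: through the last census interval."""
        return (self.n_decades - 1) * 10 + 10

    @property
    def census_years(self) -> np.ndarray:
        return self.start_year + 10 * np.arange(self.n_decades)

    def substreams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("gdp", "rain", "trees", "population")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def gen_gdp(
    n_years: int,
    start_value: float = 700.0,
    growth_rate: float = 0.014,
    noise_sd: float = 0.03,
    seed=0,
    start_year: int = 1820,
) -> AnnualSeries:
    """Geometric-growth covariate: ln(value) is a random walk with drift.

    ``seed`` may be an int or a numpy Generator.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if start_value <= 0:
        raise ValueError("start_value must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    increments = growth_rate + noise_sd * rng.standard_normal(n_years - 1)
    log_values = np.log(start_value) + np.concatenate([[0.0], np.cumsum(increments)])
    years = start_year + np.arange(n_years)
    return AnnualSeries(years, np.exp(log_values), name="gdp")


def gen_rainfall_proxy(
    n_years: int,
    mean: float = 1.2,
    ar1: float = 0.3,
    trend: float = -0.0025,
    sd: float = 0.08,
    seed=0,
    start_year: int = 1820,
    floor: float = 0.05,
) -> AnnualSeries:
    """AR(1) deviations around a linear trend, clipped at a positive floor.

    The trend line is mean + trend * (year - start_year); the stationary
    AR(1) deviation uses innovation sd ``sd`` and coefficient ``ar1``
    (initialized from the stationary distribution).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if not abs(ar1) < 1:
        raise ValueError("|ar1| must be < 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    devs = np.zeros(n_years)
    if sd > 0:
        stat_sd = sd / np.sqrt(1.0 - ar1**2)
        devs[0] = stat_sd * rng.standard_normal()
        eps = sd * rng.standard_normal(n_years - 1)
        for t in range(1, n_years):
            devs[t] = ar1 * devs[t - 1] + eps[t - 1]
    years = start_year + np.arange(n_years)
    line = mean + trend * (years - start_year)
    values = np.maximum(line + devs, floor)
    return AnnualSeries(years, values, name="rain")


def gen_tree_ring_set(
    n_trees: int,
    n_years: int,
    signal: AnnualSeries,
    age_curve_params: dict | None = None,
    noise_sd: float = 0.2,
    seed=0,
    stagger_fraction: float = 0.3,
    min_length: int = 30,
    site: str = "synthetic",
) -> TreeRingSet:
    """Ring-width series sharing ``signal`` under individual age trends.

    width_i(t) = (a_i*exp(-b_i*age) + k_i) * signal(t) * exp(N(0, noise_sd)).
    Start years are staggered uniformly over the first ``stagger_fraction``
    of the span; every series runs to the final year.
    """
    if n_trees < 2:
        raise ValueError("need at least 2 trees")
    if len(signal) < n_years:
        raise SeriesError("signal does not cover the requested span")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    curve = {**DEFAULT_AGE_CURVE, **(age_curve_params or {})}
    first_year = int(signal.years[0])
    max_offset = max(0, min(int(stagger_fraction * n_years), n_years - min_length))
    series = []
    for i in range(n_trees):
        offset = int(rng.integers(0, max_offset + 1))
        length = n_years - offset
        a = rng.uniform(*curve["a"])
        b = rng.uniform(*curve["b"])
        k = rng.uniform(*curve["k"])
        age = np.arange(length, dtype=float)
        growth_curve = a * np.exp(-b * age) + k
        sig = signal.window(first_year + offset, length)
        noise = np.exp(noise_sd * rng.standard_normal(length)) if noise_sd > 0 else 1.0
        widths = growth_curve * sig * noise
        series.append((f"SYN{i + 1:03d}", first_year + offset, widths))
    return TreeRingSet(series, site=site)


def _decadal_covariates(scenario: ScenarioConfig, gdp: AnnualSeries | None,
                        rain: AnnualSeries | None) -> tuple[np.ndarray, np.ndarray]:
    """Decadal means over [t, t+10) for each census interval start."""
    starts = scenario.census_years[:-1]
    try:
        g = (np.zeros(starts.size) if gdp is None
             else np.array([gdp.mean_over(int(y), 10) for y in starts]))
        w = (np.ones(starts.size) if rain is None
             else np.array([rain.mean_over(int(y), 10) for y in starts]))
    except SeriesError as exc:
        raise SeriesError(f"covariate gap while simulating the census: {exc}") from exc
    return g, w


def gen_population(
    scenario: ScenarioConfig,
    gdp: AnnualSeries | None = None,
    rain: AnnualSeries | None = None,
    rng: np.random.Generator | None = None,
) -> PopulationSeries:
    """Iterate X_{t+1} = X_t + R(X_t, Z_t) + eps_t on the decade grid.

    eps_t ~ N(0, process_sd^2) is process noise on the growth rate; with
    process_sd = 0 the output equals the deterministic trajectory of
    :func:`popforce.simulate.simulate_trajectory` exactly.
    """
    spec = get_spec(scenario.model)
    params = scenario.params
    params.validate(spec)
    if spec.ratio_lateral and rain is None:
        raise ModelError("ratio model needs a rainfall covariate")
    g, w = _decadal_covariates(scenario, gdp, rain)
    if rng is None:
        rng = scenario.substreams()["population"]
    n_steps = scenario.n_decades - 1
    eps = (scenario.process_sd * rng.standard_normal(n_steps)
           if scenario.process_sd > 0 else np.zeros(n_steps))
    X = np.empty(scenario.n_decades)
    X[0] = np.log(scenario.initial_pop)
    for t in range(n_steps):
        X[t + 1] = X[t] + predict_r(spec, params, X[t], g[t], w[t]) + eps[t]
    return PopulationSeries(scenario.census_years, np.exp(X), name="synthetic census")


def generate_bundle(scenario: ScenarioConfig, n_trees: int = 0,
                    tree_noise_sd: float = 0.2) -> dict:
    """All scenario inputs from one seed: gdp, rain, census, optional rings."""
    streams = scenario.substreams()
    gdp = gen_gdp(scenario.n_years, scenario.gdp_start, scenario.gdp_growth,
                  scenario.gdp_noise_sd, seed=streams["gdp"],
                  start_year=scenario.start_year)
    rain = gen_rainfall_proxy(scenario.n_years, scenario.rain_mean, scenario.rain_ar1,
                              scenario.rain_trend, scenario.rain_sd,
                              seed=streams["rain"], start_year=scenario.start_year,
                              floor=scenario.rain_floor)
    bundle = {
        "gdp": gdp,
        "rain": rain,
        "population": gen_population(scenario, gdp, rain, rng=streams["population"]),
    }
    if n_trees:
        bundle["tree_rings"] = gen_tree_ring_set(
            n_trees, scenario.n_years, rain, noise_sd=tree_noise_sd,
            seed=streams["trees"])
    return bundle


def decadal_covariates(scenario: ScenarioConfig, gdp: AnnualSeries | None,
                       rain: AnnualSeries | None) -> tuple[np.ndarray, np.ndarray]:
    """Public alias for the decade aggregation used by the generator."""
    return _decadal_covariates(scenario, gdp, rain)
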