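"""Candidate population-dynamics models with exogenous forcing.

The state variable is the log population, X_t = ln N_t, observed on a
decadal grid, and the response is the realized per-capita growth rate
R_{t+1} = X_{t+1} - X_t.  The family combines three building blocks:

* exponential growth, R = R_m (+ additive covariate terms) — a population
  in an unlimited but varying environment;
* the generalized Ricker (discrete logistic) form,
  R = R_m - exp(a*X + C), where a > 0 scales how fast competition
  intensifies with density and c = e^C is the competition constant;
* exogenous forcing by per-capita GDP (a labour-pull proxy) and a
  rainfall proxy (a tree-ring index), entering either *vertically*
  (added to R, shifting the whole R-curve up or down) or *laterally*
  (inside the exponential, shifting the equilibrium along the X axis
  without changing the slope of R at equilibrium — Royama's
  classification of perturbation geometry).

The generic response is

    R = R_m - exp(a*X + C + b_G*G + b_R*W + b_ratio*(G/W)) + v_G*G + v_R*W

with inactive terms dropped; the exponential (density-independent)
member omits the exp term entirely.  All coefficients are stored signed,
so a negative vertical GDP effect lives in v_G < 0.

The six concrete variants studied for the 1820-1960 Andean depopulation
(catalogued in :data:`MODEL_CATALOG` with their published least-squares
estimates in :data:`CATALOG_PARAMS`) are:

1. Ricker + vertical GDP
2. Ricker + lateral GDP
3. Ricker + vertical GDP + vertical rain
4. Ricker + lateral rain + vertical GDP
5. Ricker + lateral GDP + lateral rain
6. Ricker + lateral GDP/rain ratio
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelSpec",
    "ParamVector",
    "MODEL_CATALOG",
    "CATALOG_PARAMS",
    "get_spec",
    "predict_r",
    "equilibrium",
    "slope_at_equilibrium",
    "ModelError",
    "NoEquilibriumError",
]


class ModelError(ValueError):
    """Invalid model specification or parameter use."""


class NoEquilibriumError(ModelError):
    """The R-function has no positive root for the given forcing."""


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the R-function, and how.

    ``ratio_lateral`` (GDP/rain inside the exponential) is mutually
    exclusive with the separate lateral GDP/rain flags.
    """

    id: str
    density_dependence: bool = True
    gdp_vertical: bool = False
    gdp_lateral: bool = False
    rain_vertical: bool = False
    rain_lateral: bool = False
    ratio_lateral: bool = False

    def __post_init__(self) -> None:
        if self.ratio_lateral and (self.gdp_lateral or self.rain_lateral):
            raise ModelError("ratio_lateral excludes separate lateral GDP/rain terms")
        if not self.density_dependence and self.lateral_names:
            raise ModelError("lateral forcing requires density dependence")

    @property
    def lateral_names(self) -> tuple[str, ...]:
        names = []
        if self.gdp_lateral:
            names.append("b_G")
        if self.rain_lateral:
            names.append("b_R")
        if self.ratio_lateral:
            names.append("b_ratio")
        return tuple(names)

    @property
    def vertical_names(self) -> tuple[str, ...]:
        names = []
        if self.gdp_vertical:
            names.append("v_G")
        if self.rain_vertical:
            names.append("v_R")
        return tuple(names)

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["R_m"]
        if self.density_dependence:
            names += ["a", "C"]
        names += list(self.lateral_names) + list(self.vertical_names)
        return tuple(names)

    @property
    def n_structural(self) -> int:
        return len(self.param_names)

    @property
    def uses_rain(self) -> bool:
        return self.rain_vertical or self.rain_lateral or self.ratio_lateral

    @property
    def is_lateral_only(self) -> bool:
        return self.density_dependence and not self.vertical_names

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "density_dependence": self.density_dependence,
            "gdp_vertical": self.gdp_vertical,
            "gdp_lateral": self.gdp_lateral,
            "rain_vertical": self.rain_vertical,
            "rain_lateral": self.rain_lateral,
            "ratio_lateral": self.ratio_lateral,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        return cls(**data)


@dataclass(frozen=True)
class ParamVector:
    """Signed parameter values for one :class:`ModelSpec`.

    R_m is the maximum per-capita growth rate per decade; a the
    density-dependence exponent; C = ln(c) the log competition constant;
    b_* lateral and v_* vertical forcing coefficients (per covariate unit).
    """

    R_m: float = 0.0
    a: float = float("nan")
    C: float = float("nan")
    b_G: float = 0.0
    b_R: float = 0.0
    b_ratio: float = 0.0
    v_G: float = 0.0
    v_R: float = 0.0

    def validate(self, spec: ModelSpec) -> None:
        for name in spec.param_names:
            if not math.isfinite(getattr(self, name)):
                raise ModelError(f"parameter {name} missing/non-finite for model {spec.id}")
        if spec.density_dependence and self.a <= 0:
            raise ModelError("density-dependence exponent a must be > 0")

    def as_dict(self, spec: ModelSpec | None = None) -> dict:
        names = spec.param_names if spec is not None else (
            "R_m", "a", "C", "b_G", "b_R", "b_ratio", "v_G", "v_R")
        return {k: getattr(self, k) for k in names}

    def replace(self, **kw) -> "ParamVector":
        return replace(self, **kw)


# --- model catalog ---------------------------------------------------------

MODEL_CATALOG: dict[str, ModelSpec] = {
    "1": ModelSpec("1", gdp_vertical=True),
    "2": ModelSpec("2", gdp_lateral=True),
    "3": ModelSpec("3", gdp_vertical=True, rain_vertical=True),
    "4": ModelSpec("4", rain_lateral=True, gdp_vertical=True),
    "5": ModelSpec("5", gdp_lateral=True, rain_lateral=True),
    "6": ModelSpec("6", ratio_lateral=True),
    "ricker": ModelSpec("ricker"),
    "exponential": ModelSpec("exponential", density_dependence=False),
}

#: Published nonlinear-least-squares estimates for the six catalogued
#: variants (1820-1960 depopulation fit); coefficients stored signed.
CATALOG_PARAMS: dict[str, ParamVector] = {
    "1": ParamVector(R_m=1.57, a=1.08, C=-8.35, v_G=-0.0006),
    "2": ParamVector(R_m=0.041, a=4.89, C=-45.36, b_G=0.002),
    "3": ParamVector(R_m=1.39, a=1.02, C=-7.9, v_G=-0.0003, v_R=0.18),
    "4": ParamVector(R_m=1.76, a=0.86, C=-6.43, b_R=-0.10, v_G=-0.0003),
    "5": ParamVector(R_m=0.16, a=4.38, C=-35.36, b_G=0.001, b_R=-3.00),
    "6": ParamVector(R_m=0.912, a=1.11, C=-9.24, b_ratio=0.0002),
}


def get_spec(model_id) -> ModelSpec:
    key = str(model_id)
    if key not in MODEL_CATALOG:
        raise ModelError(f"unknown model id {model_id!r}; known: {sorted(MODEL_CATALOG)}")
    return MODEL_CATALOG[key]


# --- R-function ------------------------------------------------------------

_EXP_OVERFLOW = 700.0  # exp argument beyond which R is reported divergent


def lateral_forcing(spec: ModelSpec, params: ParamVector, gdp, rain):
    """The covariate part of the exponent: b_G*G + b_R*W + b_ratio*(G/W)."""
    gdp = np.asarray(gdp, dtype=float)
    rain = np.asarray(rain, dtype=float)
    force = np.zeros(np.broadcast(gdp, rain).shape)
    if spec.gdp_lateral:
        force = force + params.b_G * gdp
    if spec.rain_lateral:
        force = force + params.b_R * rain
    if spec.ratio_lateral:
        if np.any(rain <= 0):
            raise ModelError("rain must be > 0 when the GDP/rain ratio term is active")
        force = force + params.b_ratio * (gdp / rain)
    return force if force.shape else float(force)


def vertical_forcing(spec: ModelSpec, params: ParamVector, gdp, rain):
    gdp = np.asarray(gdp, dtype=float)
    rain = np.asarray(rain, dtype=float)
    force = np.zeros(np.broadcast(gdp, rain).shape)
    if spec.gdp_vertical:
        force = force + params.v_G * gdp
    if spec.rain_vertical:
        force = force + params.v_R * rain
    return force if force.shape else float(force)


def predict_r(spec: ModelSpec, params: ParamVector, X, gdp=0.0, rain=1.0):
    """Per-capita growth rate predicted by ``spec`` at log-density ``X``.

    Vectorized over X/gdp/rain.  An exponent beyond the floating-point
    overflow threshold yields ``-inf`` (a divergent R) rather than raising.
    """
    params.validate(spec)
    X = np.asarray(X, dtype=float)
    R = params.R_m + vertical_forcing(spec, params, gdp, rain)
    if spec.density_dependence:
        arg = params.a * X + params.C + lateral_forcing(spec, params, gdp, rain)
        arg = np.asarray(arg, dtype=float)
        with np.errstate(over="ignore"):
            comp = np.where(arg > _EXP_OVERFLOW, np.inf, np.exp(np.minimum(arg, _EXP_OVERFLOW)))
        R = R - comp
    out = np.asarray(R, dtype=float)
    return float(out) if out.ndim == 0 else out


# --- equilibrium analysis --------------------------------------------------

def equilibrium(spec: ModelSpec, params: ParamVector, gdp=0.0, rain=1.0) -> float:
    """Log-density X* where R = 0 (the forcing-dependent carrying capacity).

    Without vertical terms the root is closed-form,
    X* = (ln R_m - C - lateral)/a; with vertical terms it is found by
    bracketed root-finding on the (strictly decreasing) R-function.
    """
    params.validate(spec)
    if not spec.density_dependence:
        raise ModelError("exponential model has no equilibrium")
    growth = params.R_m + vertical_forcing(spec, params, gdp, rain)
    if growth <= 0:
        raise NoEquilibriumError(
            f"R_m plus vertical forcing = {growth:.4g} <= 0: no positive equilibrium")
    lat = lateral_forcing(spec, params, gdp, rain)
    if not spec.vertical_names:
        return (math.log(params.R_m) - params.C - lat) / params.a
    x_star = (math.log(growth) - params.C - lat) / params.a  # exact for this family
    # verify and fall back to brentq if the closed form drifted numerically
    if abs(predict_r(spec, params, x_star, gdp, rain)) > 1e-10:
        lo, hi = x_star - 50.0, x_star + 50.0
        x_star = brentq(lambda x: predict_r(spec, params, x, gdp, rain), lo, hi,
                        xtol=1e-12, rtol=8.9e-16)
    return float(x_star)


def slope_at_equilibrium(spec: ModelSpec, params: ParamVector, gdp=0.0, rain=1.0) -> float:
    """dR/dX at X*: the return tendency that governs local stability.

    Analytically -a * exp(a*X* + C + lateral); for purely lateral models
    this collapses to -a * R_m, independent of the forcing — the signature
    that distinguishes lateral from vertical perturbations.
    """
    x_star = equilibrium(spec, params, gdp, rain)
    lat = lateral_forcing(spec, params, gdp, rain)
    return float(-params.a * math.exp(params.a * x_star + params.C + lat))
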