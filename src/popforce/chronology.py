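"""Standardized tree-ring chronology construction and calibration.

Individual ring-width series confound a climate signal with a biological
age trend (wide juvenile rings decaying toward a mature asymptote).
Standardization removes the trend by dividing each measured width by a
fitted growth curve, yielding dimensionless indices near 1; the site
chronology is the year-by-year Tukey biweight robust mean of those
indices.  Chronology quality is summarized by rbar (the mean pairwise
inter-series correlation) and the Expressed Population Signal,

    EPS = n*rbar / (n*rbar + (1 - rbar)),

which estimates how well an n-tree chronology tracks the hypothetical
infinite-tree chronology; 0.85 is the conventional adequacy threshold
(reported here, never enforced).  Because sample depth varies through
time, chronology variance is stabilized by scaling departures from the
mean with sqrt(N_eff/max N_eff), N_eff = n/(1 + (n-1)*rbar) — an
effective-independent-sample-size approximation to the standard
variance-adjustment method.  Calibration against an instrumental series
is ordinary least squares on z-scores over the common period.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .series import AnnualSeries, SeriesError, TreeRingSet

__all__ = [
    "DetrendedSeries",
    "Chronology",
    "detrend_series",
    "detrend_set",
    "biweight_mean",
    "build_chronology",
    "eps",
    "eps_series",
    "calibrate",
    "ChronologyError",
]


class ChronologyError(ValueError):
    pass


MIN_PAIR_OVERLAP = 20  # years two series must share to enter rbar


# --- detrending ------------------------------------------------------------

@dataclass
class DetrendedSeries:
    """One series' dimensionless index = width / fitted age curve."""

    series_id: str
    years: np.ndarray
    index: np.ndarray
    curve_kind: str              # negexp | linear | mean
    curve_params: tuple

    def __len__(self) -> int:
        return self.years.size


def _negexp(t, a, b, k):
    return a * np.exp(-b * t) + k


def detrend_series(widths, years, series_id: str = "") -> DetrendedSeries:
    """Fallback cascade: negative exponential -> linear -> horizontal mean.

    The negative exponential y = a*exp(-b*t) + k is constrained to a
    decaying shape (a, b > 0, k >= 0); if the fit fails or produces a
    non-positive value anywhere, a linear regression is tried, and if its
    slope is positive (no age decay to remove) or it crosses zero, the
    series mean is used.  The index divides each width by the fitted value.
    """
    widths = np.asarray(widths, dtype=float)
    years = np.asarray(years, dtype=int)
    if widths.size != years.size:
        raise ChronologyError("widths and years differ in length")
    if widths.size < 10:
        raise ChronologyError(f"series {series_id!r}: need >= 10 observations")
    if np.any(widths < 0):
        raise ChronologyError(f"series {series_id!r}: negative widths")
    if np.all(widths == 0):
        raise ChronologyError(f"series {series_id!r}: all-zero widths")
    t = np.arange(widths.size, dtype=float)
    # a fitted "trend" that removes less than this fraction of the mean
    # width over the whole series is no age trend at all
    decay_floor = 1e-6 * float(widths.mean())

    fitted, kind, params = None, None, ()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            w0 = max(widths[0] - widths[-1], 1e-3)
            p0 = (w0, 0.02, max(widths[-1], 1e-3))
            popt, _ = curve_fit(
                _negexp, t, widths, p0=p0,
                bounds=([1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=5000)
            cand = _negexp(t, *popt)
            if np.all(cand > 0) and cand[0] - cand[-1] > decay_floor:
                fitted, kind, params = cand, "negexp", tuple(popt)
        except Exception:
            pass
    if fitted is None:
        slope, intercept = np.polyfit(t, widths, 1)
        cand = slope * t + intercept
        if slope * (widths.size - 1) < -decay_floor and np.all(cand > 0):
            fitted, kind, params = cand, "linear", (slope, intercept)
    if fitted is None:
        m = float(widths.mean())
        fitted, kind, params = np.full_like(widths, m), "mean", (m,)
    return DetrendedSeries(series_id or "series", years, widths / fitted, kind, params)


def detrend_set(tree_rings: TreeRingSet) -> list[DetrendedSeries]:
    out = []
    for sid, first_year, widths in tree_rings:
        yrs = np.arange(first_year, first_year + widths.size)
        out.append(detrend_series(widths, yrs, series_id=sid))
    return out


# --- robust location -------------------------------------------------------

def biweight_mean(values, c: float = 9.0, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Tukey's biweight location: iterated weighted mean with weights
    (1 - u^2)^2 for |u| < 1, u = (v - m)/(c*MAD), zero otherwise.

    Starts from the median; a zero MAD (over half the points tied) simply
    returns the median.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("biweight_mean needs at least one finite value")
    if v.size == 1:
        return float(v[0])
    m = float(np.median(v))
    mad = float(np.median(np.abs(v - m)))
    if mad == 0.0:
        return m
    for _ in range(max_iter):
        u = (v - m) / (c * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        m_new = float(np.sum(w * v) / np.sum(w))
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


# --- chronology ------------------------------------------------------------

@dataclass
class Chronology:
    years: np.ndarray
    index: np.ndarray
    sample_depth: np.ndarray
    rbar: float
    eps_windows: list = field(default_factory=list)  # (start, end, rbar, eps)
    stabilized_index: np.ndarray | None = None

    def __len__(self) -> int:
        return self.years.size

    def as_series(self, stabilized: bool = False, name: str = "chronology") -> AnnualSeries:
        values = self.stabilized_index if stabilized else self.index
        return AnnualSeries(self.years, values, name=name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "index": self.index,
                "stabilized_index": self.stabilized_index,
                "sample_depth": self.sample_depth,
            }
        )


def _index_matrix(detrended) -> tuple[np.ndarray, np.ndarray]:
    first = min(int(d.years[0]) for d in detrended)
    last = max(int(d.years[-1]) for d in detrended)
    years = np.arange(first, last + 1)
    mat = np.full((len(detrended), years.size), np.nan)
    for i, d in enumerate(detrended):
        mat[i, d.years - first] = d.index
    return years, mat


def _mean_interseries_correlation(mat: np.ndarray, min_overlap: int = MIN_PAIR_OVERLAP) -> float:
    """Mean pairwise Pearson r over each pair's common years.

    Pairs with fewer than ``min_overlap`` shared years, or with zero
    variance on either side, are excluded.
    """
    cors = []
    for i, j in combinations(range(mat.shape[0]), 2):
        both = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
        if both.sum() < min_overlap:
            continue
        x, y = mat[i, both], mat[j, both]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        cors.append(float(np.corrcoef(x, y)[0, 1]))
    return float(np.mean(cors)) if cors else math.nan


def eps(n: float, rbar: float) -> float:
    """Expressed Population Signal for n series with mean correlation rbar.

    Non-positive rbar carries no common signal; EPS is reported as 0 (with
    a warning) rather than a negative number.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if not -1 < rbar <= 1:
        raise ValueError("rbar must lie in (-1, 1]")
    if rbar <= 0:
        warnings.warn("rbar <= 0: no shared signal, EPS reported as 0", stacklevel=2)
        return 0.0
    return n * rbar / (n * rbar + (1.0 - rbar))


def build_chronology(detrended, min_overlap: int = MIN_PAIR_OVERLAP,
                     window: int = 30, overlap: int = 15) -> Chronology:
    """Biweight-average detrended indices into a site chronology.

    Also computes rbar, windowed EPS, and the variance-stabilized index.
    """
    detrended = list(detrended)
    if len(detrended) < 2:
        raise ChronologyError("need at least 2 detrended series")
    years, mat = _index_matrix(detrended)
    depth = np.sum(~np.isnan(mat), axis=0)
    if not np.any(depth >= 2):
        raise ChronologyError("no year is covered by >= 2 series")
    keep = depth >= 1
    years, mat, depth = years[keep], mat[:, keep], depth[keep]
    index = np.array([biweight_mean(col[~np.isnan(col)]) for col in mat.T])
    rbar = _mean_interseries_correlation(mat, min_overlap)

    chron = Chronology(years=years, index=index, sample_depth=depth, rbar=rbar)
    chron.eps_windows = eps_series(detrended, window=window, overlap=overlap,
                                   min_overlap=min_overlap)

    # variance stabilization by effective sample size
    if math.isnan(rbar) or rbar <= 0:
        chron.stabilized_index = index.copy()
    else:
        n_eff = depth / (1.0 + (depth - 1.0) * rbar)
        scale = np.sqrt(n_eff / n_eff.max())
        mean_idx = float(index.mean())
        chron.stabilized_index = mean_idx + (index - mean_idx) * scale
    return chron


def eps_series(detrended, window: int = 30, overlap: int = 15,
               min_overlap: int = MIN_PAIR_OVERLAP) -> list:
    """EPS in sliding windows: rbar and mean depth recomputed per window.

    Windows of ``window`` years step by ``overlap``; a final partial
    window is kept if it spans at least ``overlap`` years.  Returns
    (start, end, rbar, eps) tuples; windows with no valid pair yield NaN.
    """
    detrended = list(detrended)
    years, mat = _index_matrix(detrended)
    first, last = int(years[0]), int(years[-1])
    out = []
    start = first
    while start <= last:
        end = min(start + window - 1, last)
        if end - start + 1 < overlap and out:
            break
        cols = (years >= start) & (years <= end)
        sub = mat[:, cols]
        pair_overlap = min(min_overlap, max(2, (end - start + 1) // 2))
        rbar_w = _mean_interseries_correlation(sub, pair_overlap)
        depths = np.sum(~np.isnan(sub), axis=0)
        mean_n = float(depths[depths > 0].mean()) if np.any(depths > 0) else 0.0
        if math.isnan(rbar_w) or mean_n < 1:
            out.append((start, end, math.nan, math.nan))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out.append((start, end, rbar_w, eps(mean_n, rbar_w)))
        if end == last:
            break
        start += overlap
    return out


def eps_table(windows) -> pd.DataFrame:
    return pd.DataFrame(windows, columns=["win_start", "win_end", "rbar", "eps"])


# --- calibration -----------------------------------------------------------

def calibrate(chronology: AnnualSeries, instrumental: AnnualSeries,
              common_period: tuple[int, int] | None = None):
    """Regress normalized instrumental precipitation on the normalized index.

    Both series are z-scored over their common period, so the OLS slope
    equals the Pearson correlation.  Returns (slope, intercept, pearson_r).
    """
    common = np.intersect1d(chronology.years, instrumental.years)
    if common_period is not None:
        common = common[(common >= common_period[0]) & (common <= common_period[1])]
    if common.size < 10:
        raise ChronologyError(f"only {common.size} common years; need >= 10")
    x = np.array([chronology.value_at(int(y)) for y in common])
    y = np.array([instrumental.value_at(int(y)) for y in common])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ChronologyError("zero variance over the common period")
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    res = linregress(zx, zy)
    return float(res.slope), float(res.intercept), float(res.rvalue)
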