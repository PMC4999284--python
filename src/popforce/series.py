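"""Core time-series containers.

Two containers cover every input of the analysis: a decade-spaced census
series (the observed population state) and an annual covariate series
(per-capita GDP in constant dollars, or a dimensionless ring-width index
standing in for rainfall).  Both are thin, validated wrappers around numpy
arrays; heavy lifting (aggregation, alignment) lives in :mod:`demography`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnnualSeries",
    "PopulationSeries",
    "TreeRingSet",
    "SeriesError",
]


class SeriesError(ValueError):
    """Raised for malformed or inconsistent series data."""


def _as_year_array(years) -> np.ndarray:
    years = np.asarray(years, dtype=int)
    if years.ndim != 1 or years.size == 0:
        raise SeriesError("years must be a non-empty 1-D sequence")
    return years


@dataclass
class AnnualSeries:
    """A year-indexed annual covariate (GDP, rainfall proxy index, ...).

    Years must be strictly increasing and contiguous is *not* required;
    gap handling is the consumer's responsibility.
    """

    years: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.years = _as_year_array(self.years)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.years.shape:
            raise SeriesError("years and values must have equal length")
        if np.any(np.diff(self.years) <= 0):
            raise SeriesError("years must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise SeriesError(f"non-finite values in series {self.name!r}")

    def __len__(self) -> int:
        return self.years.size

    def value_at(self, year: int) -> float:
        idx = np.searchsorted(self.years, year)
        if idx >= self.years.size or self.years[idx] != year:
            raise KeyError(f"year {year} not present in series {self.name!r}")
        return float(self.values[idx])

    def window(self, start: int, length: int) -> np.ndarray:
        """Values for years ``start .. start+length-1``; raises on any gap."""
        wanted = np.arange(start, start + length)
        mask = np.isin(self.years, wanted)
        if mask.sum() != length:
            missing = sorted(set(wanted) - set(self.years[mask]))
            raise SeriesError(
                f"series {self.name!r} missing years {missing[:5]} "
                f"for window [{start}, {start + length - 1}]"
            )
        return self.values[mask]

    def mean_over(self, start: int, length: int) -> float:
        return float(self.window(start, length).mean())

    def restrict(self, start: int, end: int) -> "AnnualSeries":
        mask = (self.years >= start) & (self.years <= end)
        return AnnualSeries(self.years[mask], self.values[mask], self.name)


@dataclass
class PopulationSeries:
    """Census counts on a constant decade grid.

    ``years`` are AD integers labelling decade starts; ``counts`` are
    persons and must be strictly positive (the model state is ln N).
    """

    years: np.ndarray
    counts: np.ndarray
    name: str = "population"

    def __post_init__(self) -> None:
        self.years = _as_year_array(self.years)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.years.shape:
            raise SeriesError("years and counts must have equal length")
        steps = np.diff(self.years)
        if steps.size and (np.any(steps <= 0) or np.unique(steps).size > 1):
            raise SeriesError("census years must increase with a constant step")
        if np.any(~np.isfinite(self.counts)) or np.any(self.counts <= 0):
            raise SeriesError("population counts must be positive and finite")

    def __len__(self) -> int:
        return self.years.size

    @property
    def step(self) -> int:
        if self.years.size < 2:
            raise SeriesError("need at least two census points to infer the step")
        return int(self.years[1] - self.years[0])

    @property
    def log_counts(self) -> np.ndarray:
        return np.log(self.counts)

    def restrict(self, start: int, end: int) -> "PopulationSeries":
        mask = (self.years >= start) & (self.years <= end)
        if not mask.any():
            raise SeriesError(f"no census points inside [{start}, {end}]")
        return PopulationSeries(self.years[mask], self.counts[mask], self.name)


@dataclass
class TreeRingSet:
    """A collection of raw ring-width series from one site.

    Each entry is ``(series_id, first_year, widths_mm)`` with widths covering
    a contiguous run of years.  Widths are millimetres.
    """

    series: list = field(default_factory=list)
    site: str = ""

    def __post_init__(self) -> None:
        cleaned = []
        for sid, first_year, widths in self.series:
            widths = np.asarray(widths, dtype=float)
            if widths.ndim != 1 or widths.size == 0:
                raise SeriesError(f"series {sid!r}: empty width vector")
            if np.any(~np.isfinite(widths)) or np.any(widths < 0):
                raise SeriesError(f"series {sid!r}: widths must be finite and >= 0")
            cleaned.append((str(sid), int(first_year), widths))
        self.series = cleaned

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def years_of(self, idx: int) -> np.ndarray:
        sid, first, widths = self.series[idx]
        return np.arange(first, first + widths.size)

    @property
    def span(self) -> tuple[int, int]:
        first = min(fy for _, fy, _ in self.series)
        last = max(fy + w.size - 1 for _, fy, w in self.series)
        return first, last
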