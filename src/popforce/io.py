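"""Reading and writing the interchange formats the pipeline uses.

Series travel as two-column CSV (``year,value``).  Ring widths travel
either as long-format CSV (``series_id,year,width_mm``) or as Tucson RWL,
the decadal-row dendrochronology interchange format: each line carries a
series id, the decade-start year, and up to ten integer widths, with a
sentinel (``999`` for 0.01 mm files, ``-9999`` for 0.001 mm files) closing
the series.  We write 0.001 mm files and accept both dialects on read.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .series import AnnualSeries, PopulationSeries, SeriesError, TreeRingSet

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_rwl",
    "write_rwl",
    "read_rings_csv",
    "write_rings_csv",
]


def read_series_csv(path, kind: str = "annual", name: str | None = None):
    """Read a two-column ``year,value`` CSV into a series container.

    ``kind`` selects the container: ``"annual"`` -> :class:`AnnualSeries`,
    ``"population"`` -> :class:`PopulationSeries`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SeriesError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise SeriesError(f"{path}: expected two columns (year,value)")
    df = df.iloc[:, :2]
    df.columns = ["year", "value"]
    for col in df.columns:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            line = int(bad.index[0]) + 2  # header is line 1
            raise SeriesError(f"{path}:{line}: non-numeric {col} {bad.iloc[0][col]!r}")
    df = df.astype({"year": int, "value": float}).sort_values("year")
    dup = df["year"].duplicated()
    if dup.any():
        raise SeriesError(f"{path}: duplicate year {int(df['year'][dup].iloc[0])}")
    if df.empty:
        raise SeriesError(f"{path}: empty series")
    name = name if name is not None else path.stem
    if kind == "annual":
        return AnnualSeries(df["year"].to_numpy(), df["value"].to_numpy(), name)
    if kind == "population":
        return PopulationSeries(df["year"].to_numpy(), df["value"].to_numpy(), name)
    raise ValueError(f"unknown series kind {kind!r}")


def write_series_csv(series, path) -> None:
    values = series.counts if isinstance(series, PopulationSeries) else series.values
    pd.DataFrame({"year": series.years, "value": values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tucson RWL
# ---------------------------------------------------------------------------

_STOP_MARKS = {999, -9999}


def write_rwl(tree_rings: TreeRingSet, path, precision: float = 0.001) -> None:
    """Write ring widths as Tucson decadal rows, units 0.001 mm, -9999 stop."""
    lines = []
    for sid, first_year, widths in tree_rings:
        ident = sid[:8]
        values = np.round(widths / precision).astype(int).tolist()
        values.append(-9999)
        year = first_year
        pos = 0
        while pos < len(values):
            row_start = year
            n_in_row = 10 - (row_start % 10)
            chunk = values[pos : pos + n_in_row]
            cells = "".join(f"{v:6d}" for v in chunk)
            lines.append(f"{ident:<8s}{row_start:4d}{cells}")
            pos += len(chunk)
            year = row_start + len(chunk)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_rwl(path) -> TreeRingSet:
    """Parse Tucson RWL into mm-valued series.

    Handles both stop-mark dialects: ``999`` means the file stores 0.01 mm
    units, ``-9999`` means 0.001 mm; the sentinel is excluded from the data.
    """
    path = Path(path)
    raw: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        ident = line[:8].strip()
        try:
            year = int(line[8:12])
        except ValueError as exc:
            raise SeriesError(f"{path}:{lineno}: bad decade year in series {ident!r}") from exc
        try:
            cells = [int(tok) for tok in line[12:].split()]
        except ValueError as exc:
            raise SeriesError(f"{path}:{lineno}: non-integer width in series {ident!r}") from exc
        values = raw.setdefault(ident, [])
        values.extend((year + k, cell) for k, cell in enumerate(cells))
    series = []
    for ident, pairs in raw.items():
        if not pairs:
            continue
        # the dialect is decided by the series' closing sentinel: 999 marks
        # a 0.01 mm file (where 999 cannot be data), -9999 a 0.001 mm file
        # (where an interior 999 is a genuine 0.999 mm ring)
        last = pairs[-1][1]
        if last not in _STOP_MARKS:
            raise SeriesError(f"{path}: series {ident!r} missing its stop mark")
        scale = 0.01 if last == 999 else 0.001
        pairs = pairs[:-1]
        if not pairs:
            continue
        years = np.array([y for y, _ in pairs])
        if np.any(np.diff(years) != 1):
            raise SeriesError(f"{path}: series {ident!r} has non-contiguous years")
        widths = np.array([float(w) for _, w in pairs]) * scale
        series.append((ident, int(years[0]), widths))
    if not series:
        raise SeriesError(f"{path}: no ring-width series found")
    return TreeRingSet(series, site=path.stem)


# ---------------------------------------------------------------------------
# Long-format ring CSV
# ---------------------------------------------------------------------------

def write_rings_csv(tree_rings: TreeRingSet, path) -> None:
    rows = []
    for sid, first_year, widths in tree_rings:
        for i, w in enumerate(widths):
            rows.append((sid, first_year + i, w))
    pd.DataFrame(rows, columns=["series_id", "year", "width_mm"]).to_csv(path, index=False)


def read_rings_csv(path) -> TreeRingSet:
    df = pd.read_csv(path)
    needed = {"series_id", "year", "width_mm"}
    if not needed.issubset(df.columns):
        raise SeriesError(f"{path}: expected columns {sorted(needed)}")
    series = []
    for sid, group in df.groupby("series_id", sort=True):
        group = group.sort_values("year")
        years = group["year"].to_numpy(dtype=int)
        if np.any(np.diff(years) != 1):
            raise SeriesError(f"{path}: series {sid!r} has non-contiguous years")
        series.append((str(sid), int(years[0]), group["width_mm"].to_numpy(dtype=float)))
    return TreeRingSet(series, site=Path(path).stem)
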