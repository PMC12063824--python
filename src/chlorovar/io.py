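"""Tabular containers and CSV readers/writers for the monitoring pipeline.

Three kinds of record move through the analysis:

* :class:`SondeSeries` — in-situ sonde measurements (temperature, salinity,
  chlorophyll) at one site, on a 15-minute or calendar-day grid;
* :class:`MetSeries` — daily meteorology (average and maximum sustained wind
  speed, rainfall);
* :class:`DailySeries` — the QC'd daily-average product, carrying a
  per-date/per-variable provenance label.

Timestamps are naive local time; dates are calendar dates at the site.  A
missing value is an empty CSV field and a ``NaN`` internally — zero is a
legal measurement and never means missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

SONDE_VARIABLES = ("temperature", "salinity", "chlorophyll")
MET_VARIABLES = ("wind_avg", "wind_max", "rain")
CADENCES = ("15-min", "daily")

#: Provenance labels for daily-average values.
OBSERVED_COMPLETE = "observed_complete"
GAP_FILLED = "gap_filled"
OMITTED = "omitted"

_STEP = pd.Timedelta(minutes=15)


def _parse_timestamps(raw: pd.Series, path: str) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: row {row + 2}: malformed timestamp {raw.iloc[row]!r}")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ParseError(f"{path}: row {row + 2}: empty timestamp")
    return pd.DatetimeIndex(parsed)


def _check_strictly_increasing(index: pd.DatetimeIndex, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValidationError(f"{what}: duplicated timestamp {dup}")
    if not index.is_monotonic_increasing:
        raise ValidationError(f"{what}: timestamps are not increasing")


@dataclass
class SondeSeries:
    """Timestamped sonde record at one site.

    ``data`` is indexed by naive timestamps and has the three sonde columns;
    any cell may be NaN.  The index must be strictly increasing and lie on
    the cadence grid (quarter-hour marks for 15-min, midnight for daily).
    """

    site: str
    cadence: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.cadence not in CADENCES:
            raise ValidationError(f"cadence must be one of {CADENCES}")
        missing = [v for v in SONDE_VARIABLES if v not in self.data.columns]
        if missing:
            raise ValidationError(f"sonde series lacks columns {missing}")
        idx = pd.DatetimeIndex(self.data.index)
        _check_strictly_increasing(idx, f"sonde series {self.site}")
        if len(idx):
            if self.cadence == "15-min":
                off_grid = (idx.minute % 15 != 0) | (idx.second != 0)
            else:
                off_grid = idx != idx.normalize()
            if off_grid.any():
                raise ValidationError(
                    f"sonde series {self.site}: timestamp {idx[off_grid][0]} off the "
                    f"{self.cadence} grid"
                )
        chl = self.data["chlorophyll"]
        if (chl.dropna() < 0).any():
            raise ValidationError(f"sonde series {self.site}: negative chlorophyll")
        self.data = self.data[list(SONDE_VARIABLES)].astype(float)
        self.data.index = idx
        self.data.index.name = "timestamp"

    def on_grid(self) -> pd.DataFrame:
        """Data reindexed to the complete cadence grid between first and last
        timestamp; rows never logged appear as all-NaN."""
        if self.data.empty:
            return self.data.copy()
        step = _STEP if self.cadence == "15-min" else pd.Timedelta(days=1)
        grid = pd.date_range(self.data.index[0], self.data.index[-1], freq=step,
                             name="timestamp")
        return self.data.reindex(grid)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class MetSeries:
    """Daily meteorology: average/maximum wind speed (m/s) and rain (mm/day)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [v for v in MET_VARIABLES if v not in self.data.columns]
        if missing:
            raise ValidationError(f"met series lacks columns {missing}")
        idx = pd.DatetimeIndex(self.data.index).normalize()
        _check_strictly_increasing(idx, "met series")
        df = self.data[list(MET_VARIABLES)].astype(float)
        both = df["wind_avg"].notna() & df["wind_max"].notna()
        if (df.loc[both, "wind_max"] < df.loc[both, "wind_avg"]).any():
            bad = df.loc[both].index[
                (df.loc[both, "wind_max"] < df.loc[both, "wind_avg"]).to_numpy()
            ][0]
            raise ValidationError(f"met series: wind_max < wind_avg on {bad.date()}")
        for col in MET_VARIABLES:
            if (df[col].dropna() < 0).any():
                raise ValidationError(f"met series: negative {col}")
        df.index = idx
        df.index.name = "date"
        self.data = df

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DailySeries:
    """QC'd daily averages at one site, with per-variable provenance.

    ``provenance`` has the same shape as ``data`` and holds one of
    ``observed_complete`` / ``gap_filled`` / ``omitted`` per cell (NaN where
    the date was never inside a deployment for that variable).  An omitted
    cell carries no value.
    """

    site: str
    data: pd.DataFrame
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [v for v in SONDE_VARIABLES if v not in self.data.columns]
        if missing:
            raise ValidationError(f"daily series lacks columns {missing}")
        idx = pd.DatetimeIndex(self.data.index).normalize()
        _check_strictly_increasing(idx, f"daily series {self.site}")
        df = self.data[list(SONDE_VARIABLES)].astype(float)
        df.index = idx
        df.index.name = "date"
        self.data = df
        if self.provenance is not None:
            prov = self.provenance.reindex(index=idx, columns=list(SONDE_VARIABLES))
            omitted = prov == OMITTED
            if df.where(omitted).notna().any().any():
                raise ValidationError(
                    f"daily series {self.site}: omitted cell carries a value"
                )
            self.provenance = prov

    def chlorophyll(self) -> pd.Series:
        return self.data["chlorophyll"]

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# CSV round-trip


def read_sonde_csv(path: str | Path, cadence: str, site: str | None = None) -> SondeSeries:
    """Read a sonde CSV (columns ``timestamp, temperature, salinity,
    chlorophyll``, optional ``site``) into a validated :class:`SondeSeries`.

    Missing cells stay missing; a malformed timestamp raises
    :class:`ParseError` naming the row; non-monotone timestamps raise
    :class:`ValidationError`.
    """
    df = pd.read_csv(path)
    required = {"timestamp", *SONDE_VARIABLES}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: header must name {sorted(required)}")
    idx = _parse_timestamps(df["timestamp"], str(path))
    if site is None:
        site = str(df["site"].iloc[0]) if "site" in df.columns and len(df) else "unknown"
    data = df[list(SONDE_VARIABLES)].copy()
    data.index = idx
    return SondeSeries(site=site, cadence=cadence, data=data)


def write_sonde_csv(series: SondeSeries, path: str | Path) -> None:
    fmt = "%Y-%m-%dT%H:%M" if series.cadence == "15-min" else "%Y-%m-%d"
    out = series.data.copy()
    out.insert(0, "site", series.site)
    out.index = out.index.strftime(fmt)
    out.index.name = "timestamp"
    out.to_csv(path)


def read_daily_csv(path: str | Path, site: str | None = None) -> DailySeries:
    """Read a daily-average CSV (column ``date`` plus the sonde variables)."""
    df = pd.read_csv(path)
    required = {"date", *SONDE_VARIABLES}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: header must name {sorted(required)}")
    idx = _parse_timestamps(df["date"], str(path))
    if site is None:
        site = str(df["site"].iloc[0]) if "site" in df.columns and len(df) else "unknown"
    data = df[list(SONDE_VARIABLES)].copy()
    data.index = idx
    return DailySeries(site=site, data=data)


def write_daily_csv(series: DailySeries, path: str | Path) -> None:
    out = series.data.copy()
    out.insert(0, "site", series.site)
    out.index = out.index.strftime("%Y-%m-%d")
    out.index.name = "date"
    out.to_csv(path)


def read_met_csv(path: str | Path) -> MetSeries:
    """Read a meteorology CSV (``date, wind_avg, wind_max, rain``)."""
    df = pd.read_csv(path)
    required = {"date", *MET_VARIABLES}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: header must name {sorted(required)}")
    idx = _parse_timestamps(df["date"], str(path))
    data = df[list(MET_VARIABLES)].copy()
    data.index = idx
    return MetSeries(data=data)


def write_met_csv(series: MetSeries, path: str | Path) -> None:
    out = series.data.copy()
    out.index = out.index.strftime("%Y-%m-%d")
    out.index.name = "date"
    out.to_csv(path)


def average_rain_stations(stations: Sequence[pd.Series]) -> pd.Series:
    """Per-date arithmetic mean of rain over the stations reporting that date.

    Dates reported by no station stay missing.  Mirrors the convention of
    averaging a small network of nearby gauges without requiring every gauge
    to report every day.
    """
    if len(stations) == 0:
        raise ValidationError("need at least one rain station")
    frames = []
    for i, s in enumerate(stations):
        s = pd.Series(s, dtype=float)
        s.index = pd.DatetimeIndex(s.index).normalize()
        if (s.dropna() < 0).any():
            raise ValidationError(f"rain station {i}: negative rain")
        frames.append(s.rename(i))
    merged = pd.concat(frames, axis=1).sort_index()
    return merged.mean(axis=1, skipna=True).rename("rain")
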