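"""Sensor QC: 15-minute sonde records to daily averages.

High-frequency records are converted to daily averages to remove diel
signatures.  Two rules govern the conversion:

* short gaps in the 15-minute record are filled by linear interpolation
  before averaging;
* a daily average is omitted if more than one consecutive hour of raw data
  (i.e. a run of more than four 15-minute points) is missing within that
  24-hour period — the inequality is strict, so an exactly 60-minute gap is
  tolerated and a 75-minute gap is not.

Gap length is always assessed on the raw (pre-interpolation) record,
per variable.  A run of missingness that spans midnight counts toward each
day only for the portion inside that day's window.  Partial days at
deployment boundaries are retained only when the deployment covers at least
23 hours of the day; interpolation never extrapolates beyond the first and
last observed point of a deployment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    GAP_FILLED,
    OBSERVED_COMPLETE,
    OMITTED,
    SONDE_VARIABLES,
    DailySeries,
    SondeSeries,
)

_STEP_MIN = 15
_SLOTS_PER_DAY = 96
#: Minimum deployment coverage of a day, in 15-min slots, for the day to be
#: eligible at all (23 hours).
_MIN_COVERED_SLOTS = 92


def fill_gaps_linear(series: SondeSeries, variable: str) -> SondeSeries:
    """Fill internal gaps in one variable of a 15-min record by linear
    interpolation between the bracketing observations.

    Leading and trailing gaps (before the first / after the last observed
    point) remain missing; observed points are unchanged.
    """
    if variable not in SONDE_VARIABLES:
        raise ValidationError(f"unknown variable {variable!r}")
    if series.cadence != "15-min":
        raise ValidationError("fill_gaps_linear expects a 15-min series")
    grid = series.on_grid()
    grid[variable] = grid[variable].interpolate(method="linear", limit_area="inside")
    return SondeSeries(site=series.site, cadence="15-min", data=grid)


def _longest_missing_run(missing: np.ndarray) -> int:
    """Length (in points) of the longest run of True in a boolean vector."""
    best = run = 0
    for m in missing:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def daily_average(
    series: SondeSeries, variable: str, qc_max_gap: int = 60
) -> tuple[pd.Series, pd.DataFrame]:
    """Daily averages of one variable with the gap-omission rule applied.

    Returns ``(values, report)`` where ``values`` is indexed by date (NaN on
    omitted days) and ``report`` has per-date columns ``n_observed``,
    ``longest_gap_min`` and ``provenance``.
    """
    if variable not in SONDE_VARIABLES:
        raise ValidationError(f"unknown variable {variable!r}")
    if series.cadence != "15-min":
        raise ValidationError("daily_average expects a 15-min series")

    grid = series.on_grid()
    raw = grid[variable]
    filled = raw.interpolate(method="linear", limit_area="inside")

    obs_idx = raw.dropna().index
    dates, values, n_obs, gaps, prov = [], [], [], [], []
    if len(obs_idx) == 0:
        report = pd.DataFrame(
            columns=["n_observed", "longest_gap_min", "provenance"],
            index=pd.DatetimeIndex([], name="date"),
        )
        return pd.Series(dtype=float, name=variable), report

    first, last = obs_idx[0], obs_idx[-1]
    covered = pd.Series((raw.index >= first) & (raw.index <= last), index=raw.index)

    for day, day_raw in raw.groupby(raw.index.normalize()):
        day_cov = day_raw[covered.loc[day_raw.index].to_numpy()]
        n_observed = int(day_cov.notna().sum())
        missing = day_cov.isna().to_numpy()
        longest = _longest_missing_run(missing) * _STEP_MIN

        dates.append(day)
        n_obs.append(n_observed)
        gaps.append(longest)
        if len(day_cov) < _MIN_COVERED_SLOTS:
            values.append(np.nan)
            prov.append(OMITTED)
        elif longest > qc_max_gap:
            values.append(np.nan)
            prov.append(OMITTED)
        else:
            values.append(float(filled.loc[day_cov.index].mean()))
            prov.append(GAP_FILLED if missing.any() else OBSERVED_COMPLETE)

    idx = pd.DatetimeIndex(dates, name="date")
    report = pd.DataFrame(
        {"n_observed": n_obs, "longest_gap_min": gaps, "provenance": prov}, index=idx
    )
    return pd.Series(values, index=idx, name=variable), report


def to_daily(
    series: SondeSeries, qc_max_gap: int = 60, variables: tuple[str, ...] = SONDE_VARIABLES
) -> tuple[DailySeries, pd.DataFrame]:
    """Convert a 15-min sonde record to a :class:`DailySeries` covering all
    variables, plus a long-format QC report (date, variable, n_observed,
    longest_gap_min, provenance)."""
    cols, provs, reports = {}, {}, []
    for var in variables:
        vals, report = daily_average(series, var, qc_max_gap=qc_max_gap)
        cols[var] = vals
        provs[var] = report["provenance"]
        report = report.assign(variable=var)
        reports.append(report)
    data = pd.DataFrame(cols)
    for var in SONDE_VARIABLES:
        if var not in data.columns:
            data[var] = np.nan
    provenance = pd.DataFrame(provs).reindex(columns=list(SONDE_VARIABLES))
    daily = DailySeries(site=series.site, data=data, provenance=provenance)
    qc_report = pd.concat(reports).rename_axis("date").reset_index()
    return daily, qc_report
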