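"""Shared fixtures: small hand-built series and CSV writers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chlorovar.io import DailySeries, MetSeries, SondeSeries


def make_daily(values, start="2015-07-01", site="BB3", temperature=None, salinity=None):
    """DailySeries from a chlorophyll list (None -> missing)."""
    idx = pd.date_range(start, periods=len(values), freq="D")
    chl = [np.nan if v is None else float(v) for v in values]
    data = pd.DataFrame(
        {
            "temperature": temperature if temperature is not None else 25.0,
            "salinity": salinity if salinity is not None else 30.0,
            "chlorophyll": chl,
        },
        index=idx,
    )
    return DailySeries(site=site, data=data)


def make_met(n_days, start="2015-06-15", wind_avg=5.0, wind_max=8.0, rain=0.0, seed=None):
    idx = pd.date_range(start, periods=n_days, freq="D")
    if seed is not None:
        rng = np.random.default_rng(seed)
        wa = np.abs(rng.normal(wind_avg, 1.5, n_days))
        wm = wa * 1.4 + np.abs(rng.normal(0, 1.0, n_days))
        rn = np.where(rng.random(n_days) < 0.3, rng.gamma(1.0, 5.0, n_days), 0.0)
    else:
        wa = np.full(n_days, float(wind_avg))
        wm = np.full(n_days, float(wind_max))
        rn = np.full(n_days, float(rain))
    return MetSeries(data=pd.DataFrame({"wind_avg": wa, "wind_max": wm, "rain": rn}, index=idx))


def make_15min(values_by_day, start="2015-07-01", site="BB3"):
    """SondeSeries on the full 15-min grid; values_by_day is a list of
    per-day chlorophyll arrays of length 96 (np.nan for missing)."""
    n_days = len(values_by_day)
    idx = pd.date_range(start, periods=n_days * 96, freq="15min")
    chl = np.concatenate([np.asarray(v, dtype=float) for v in values_by_day])
    data = pd.DataFrame(
        {"temperature": 25.0, "salinity": 30.0, "chlorophyll": chl}, index=idx
    )
    return SondeSeries(site=site, cadence="15-min", data=data)


@pytest.fixture
def rng():
    return np.random.default_rng(20150710)
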