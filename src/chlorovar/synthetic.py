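"""Synthetic monitoring data with known ground truth.

The generator emulates the statistical regimes of a shallow, wind-driven,
long-residence-time subtropical lagoon:

* daily chlorophyll built multiplicatively from a grand mean, annual factors,
  unit-mean monthly (seasonal) factors, ephemeral wind-triggered bloom
  kernels, and mean-one lognormal noise — so the daily distribution is
  right-skewed and the multiplicative decomposition's components are
  recoverable by construction;
* meteorology with a seasonal-mean AR(1) wind, gusty daily maxima, and
  Bernoulli–gamma rainfall;
* a seasonal temperature sinusoid (roughly 10–30 °C) and a salinity random
  walk pulled down sharply by rain and up slowly by evaporation;
* a 15-minute variant with a diel signal and planted gaps, for QC tests;
* a monthly grab-sample program with optional skipped months.

Every stochastic step is seeded, and every planted bloom is recorded in a
ledger so detection and driver-recovery tests can compare against truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import OBSERVED_COMPLETE, DailySeries, MetSeries, SondeSeries

_DEFAULT_ANNUAL = (1.35, 1.15, 1.0, 0.85, 0.65)  # gentle multi-year decline, mean 1


def _default_monthly() -> tuple[float, ...]:
    # cosine peaked between June and July; mean over the 12 months is exactly 1
    j = np.arange(1, 13)
    return tuple(1.0 + 0.35 * np.cos(2 * np.pi * (j - 6.5) / 12.0))


@dataclass
class WindModel:
    mean: float = 5.5  # m/s
    seasonal_amplitude: float = 1.0  # m/s
    peak_doy: int = 105  # windy spring
    ar1: float = 0.6
    innovation_sd: float = 1.5  # m/s
    gust_factor: float = 1.4  # wind_max = gust_factor * wind_avg + |noise|
    gust_sd: float = 2.0  # independent gust scatter, m/s (r(avg,max) ~ 0.9)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1 < 1.0:
            raise ValidationError("AR(1) coefficient must lie in [0, 1)")
        if self.gust_factor < 1.0:
            raise ValidationError("gust_factor must be >= 1")


@dataclass
class RainModel:
    wet_prob: float = 0.15
    gamma_shape: float = 0.6
    gamma_scale: float = 12.0  # mm


@dataclass
class TemperatureModel:
    mean: float = 20.0  # °C
    amplitude: float = 10.0  # °C; 10–30 °C annual range
    peak_doy: int = 196  # mid-July
    noise_sd: float = 0.6


@dataclass
class SalinityModel:
    baseline: float = 30.0
    rain_sensitivity: float = 0.15  # salinity drop per mm of rain
    evaporative_drift: float = 0.03  # per day
    minimum: float = 8.0
    maximum: float = 46.0
    noise_sd: float = 0.15


@dataclass
class BloomModel:
    """Wind-triggered ephemeral bloom kernels."""

    trigger_quantile: float = 0.90  # monthly wind percentile that triggers a bloom
    lag_days: int = 0  # chlorophyll responds this many days after the wind
    amplitude_low: float = 1.5  # relative kernel peak (fraction of baseline)
    amplitude_high: float = 4.0
    rise_days: tuple[int, int] = (1, 3)
    fall_days: tuple[int, int] = (1, 3)
    refractory_days: int = 30


@dataclass
class PlantedBloom:
    """An explicitly placed bloom kernel (driver 'none')."""

    peak_date: str | pd.Timestamp
    rel_amplitude: float
    rise_days: int = 1
    fall_days: int = 1


@dataclass
class SyntheticTruth:
    """Ground-truth parameters for one synthetic scenario."""

    c_true: float = 50.0  # µg/L grand mean
    annual_factors: tuple[float, ...] = _DEFAULT_ANNUAL
    monthly_factors: tuple[float, ...] = field(default_factory=_default_monthly)
    noise_sigma: float = 0.35  # lognormal sigma of the residual factor
    wind: WindModel = field(default_factory=WindModel)
    rain: RainModel = field(default_factory=RainModel)
    temperature: TemperatureModel = field(default_factory=TemperatureModel)
    salinity: SalinityModel = field(default_factory=SalinityModel)
    blooms: BloomModel | None = field(default_factory=BloomModel)
    planted_blooms: tuple[PlantedBloom, ...] = ()

    def __post_init__(self) -> None:
        if self.c_true <= 0:
            raise ValidationError("c_true must be positive")
        if any(f <= 0 for f in self.annual_factors):
            raise ValidationError("annual factors must be positive")
        if len(self.monthly_factors) != 12 or any(f <= 0 for f in self.monthly_factors):
            raise ValidationError("monthly_factors must be 12 positive values")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")

    def annual_factor(self, year: int, start_year: int) -> float:
        return self.annual_factors[(year - start_year) % len(self.annual_factors)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _seasonal(doy: np.ndarray, mean: float, amplitude: float, peak_doy: int) -> np.ndarray:
    return mean + amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def generate_met(
    truth: SyntheticTruth, start: str | pd.Timestamp, n_days: int, seed: int
) -> MetSeries:
    """Seasonal AR(1) wind (floored at zero), gusty maxima, Bernoulli–gamma
    rain."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(pd.Timestamp(start).normalize(), periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    w = truth.wind
    mu = _seasonal(doy, w.mean, w.seasonal_amplitude, w.peak_doy)
    z = np.zeros(n_days)
    innov = rng.normal(0.0, w.innovation_sd, size=n_days)
    for t in range(1, n_days):
        z[t] = w.ar1 * z[t - 1] + innov[t]
    z[0] = innov[0]
    wind_avg = np.maximum(mu + z, 0.0)
    wind_max = wind_avg * w.gust_factor + np.abs(rng.normal(0.0, w.gust_sd, n_days))

    r = truth.rain
    wet = rng.random(n_days) < r.wet_prob
    rain = np.where(wet, rng.gamma(r.gamma_shape, r.gamma_scale, n_days), 0.0)

    return MetSeries(
        data=pd.DataFrame(
            {"wind_avg": wind_avg, "wind_max": wind_max, "rain": rain}, index=dates
        )
    )


def _triangular_kernel(n_days: int, peak: int, amp: float, rise: int, fall: int) -> np.ndarray:
    k = np.zeros(n_days)
    for i in range(rise + 1):
        t = peak - rise + i
        if 0 <= t < n_days:
            k[t] = max(k[t], amp * i / rise) if rise else amp
    for j in range(1, fall + 1):
        t = peak + j
        if 0 <= t < n_days:
            k[t] = max(k[t], amp * (1.0 - j / fall))
    return k


def generate_daily_chl(
    truth: SyntheticTruth, met: MetSeries, seed: int, site: str = "SYN"
) -> tuple[DailySeries, list[dict]]:
    """Daily chlorophyll, temperature and salinity over the met record.

    Chlorophyll is ``c_true * Y(year) * M(month) * (1 + sum of bloom
    kernels) * exp(eps)`` with ``eps ~ Normal(-sigma^2/2, sigma^2)`` so the
    noise factor has mean one.  Wind-driven kernels are planted where the
    (lagged) daily average wind exceeds its month-of-year 90th-percentile;
    every kernel is returned in the ledger with its peak date and amplitude
    in µg/L.
    """
    rng = np.random.default_rng(seed)
    dates = met.data.index
    n = len(dates)
    start_year = int(dates[0].year)
    yearf = np.array([truth.annual_factor(int(d.year), start_year) for d in dates])
    monthf = np.array([truth.monthly_factors[d.month - 1] for d in dates])
    base = truth.c_true * yearf * monthf

    kernel = np.zeros(n)
    ledger: list[dict] = []

    if truth.planted_blooms:
        for pb in truth.planted_blooms:
            peak = pd.Timestamp(pb.peak_date).normalize()
            if peak not in dates:
                raise ValidationError(f"planted bloom peak {peak.date()} outside record")
            pos = int(dates.get_loc(peak))
            kernel += _triangular_kernel(n, pos, pb.rel_amplitude, pb.rise_days, pb.fall_days)
            ledger.append(
                {
                    "peak_date": peak,
                    "amplitude_ugl": pb.rel_amplitude * base[pos],
                    "rel_amplitude": pb.rel_amplitude,
                    "rise_days": pb.rise_days,
                    "fall_days": pb.fall_days,
                    "driver": "none",
                    "lag_days": 0,
                }
            )
    elif truth.blooms is not None:
        b = truth.blooms
        wind = met.data["wind_avg"]
        # month-of-year exceedance threshold ("seasonal 90th percentile")
        q = wind.groupby(wind.index.month).transform(
            lambda s: s.quantile(b.trigger_quantile)
        )
        exceed = (wind > q).to_numpy()
        last_peak = -10**9
        for t in range(n):
            src = t - b.lag_days
            if src < 0 or not exceed[src]:
                continue
            rise = int(rng.integers(b.rise_days[0], b.rise_days[1] + 1))
            fall = int(rng.integers(b.fall_days[0], b.fall_days[1] + 1))
            peak_pos = t + rise
            if peak_pos >= n or peak_pos - last_peak < b.refractory_days:
                continue
            amp = float(rng.uniform(b.amplitude_low, b.amplitude_high))
            kernel += _triangular_kernel(n, peak_pos, amp, rise, fall)
            last_peak = peak_pos
            ledger.append(
                {
                    "peak_date": dates[peak_pos],
                    "amplitude_ugl": amp * base[peak_pos],
                    "rel_amplitude": amp,
                    "rise_days": rise,
                    "fall_days": fall,
                    "driver": "wind",
                    "lag_days": b.lag_days,
                }
            )

    if truth.noise_sigma > 0:
        eps = rng.normal(-0.5 * truth.noise_sigma**2, truth.noise_sigma, n)
        noise = np.exp(eps)
    else:
        noise = np.ones(n)
    chl = base * (1.0 + kernel) * noise

    tm = truth.temperature
    temp = _seasonal(dates.dayofyear.to_numpy(), tm.mean, tm.amplitude, tm.peak_doy)
    temp = temp + rng.normal(0.0, tm.noise_sd, n)

    sm = truth.salinity
    rain = met.data["rain"].to_numpy()
    sal = np.empty(n)
    sal[0] = sm.baseline
    sal_noise = rng.normal(0.0, sm.noise_sd, n)
    for t in range(1, n):
        sal[t] = sal[t - 1] + sm.evaporative_drift - sm.rain_sensitivity * rain[t]
        sal[t] = np.clip(sal[t] + sal_noise[t], sm.minimum, sm.maximum)

    data = pd.DataFrame(
        {"temperature": temp, "salinity": sal, "chlorophyll": chl}, index=dates
    )
    prov = pd.DataFrame(OBSERVED_COMPLETE, index=dates, columns=list(data.columns))
    return DailySeries(site=site, data=data, provenance=prov), ledger


def generate_15min(
    daily: DailySeries,
    diel_amplitude: float = 0.15,
    gap_spec: tuple[tuple[str | pd.Timestamp, int], ...] = (),
    seed: int = 0,
    noise_sd: float = 0.0,
) -> SondeSeries:
    """Expand a daily record onto the 15-minute grid.

    Each day's 96 chlorophyll points are the daily value times
    ``1 + diel_amplitude * sin(2*pi*hour/24)`` plus optional Gaussian noise;
    temperature and salinity are held at their daily values (plus noise).
    ``gap_spec`` is a list of ``(start timestamp, duration minutes)`` blanked
    from every variable; overlapping gaps are an error.
    """
    rng = np.random.default_rng(seed)
    days = daily.data.index
    grid = pd.date_range(days[0], days[-1] + pd.Timedelta(hours=23, minutes=45), freq="15min")
    hours = grid.hour.to_numpy() + grid.minute.to_numpy() / 60.0
    diel = 1.0 + diel_amplitude * np.sin(2 * np.pi * hours / 24.0)

    day_vals = daily.data.reindex(grid.normalize())
    chl = day_vals["chlorophyll"].to_numpy() * diel
    temp = day_vals["temperature"].to_numpy().copy()
    sal = day_vals["salinity"].to_numpy().copy()
    if noise_sd > 0:
        chl = np.maximum(chl + rng.normal(0.0, noise_sd, len(grid)), 0.0)
        temp = temp + rng.normal(0.0, noise_sd, len(grid))
        sal = sal + rng.normal(0.0, noise_sd, len(grid))

    data = pd.DataFrame(
        {"temperature": temp, "salinity": sal, "chlorophyll": chl}, index=grid
    )

    intervals = []
    for start, duration in gap_spec:
        s = pd.Timestamp(start)
        e = s + pd.Timedelta(minutes=int(duration))
        for s2, e2 in intervals:
            if s < e2 and s2 < e:
                raise ValidationError(f"overlapping gaps at {s}")
        intervals.append((s, e))
        mask = (data.index >= s) & (data.index < e)
        data.loc[mask, :] = np.nan

    return SondeSeries(site=daily.site, cadence="15-min", data=data)


def generate_monthly_program(
    daily: DailySeries,
    day_rule: int | str = 15,
    skip: tuple[tuple[int, int], ...] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """One grab sample per month from a multi-year daily record.

    ``day_rule`` is either a fixed day-of-month or ``"random"``; months in
    ``skip`` (year, month) are omitted, emulating weather-prevented sampling.
    Returns a DataFrame with columns ``date`` and ``chlorophyll``.
    """
    rng = np.random.default_rng(seed)
    chl = daily.chlorophyll().dropna()
    rows = []
    for (year, month), month_chl in chl.groupby([chl.index.year, chl.index.month]):
        if (int(year), int(month)) in {(int(y), int(m)) for y, m in skip}:
            continue
        if day_rule == "random":
            date = month_chl.index[rng.integers(len(month_chl))]
        else:
            target = int(day_rule)
            pos = int(np.argmin(np.abs(month_chl.index.day - target)))
            date = month_chl.index[pos]
        rows.append({"date": date, "chlorophyll": float(month_chl.loc[date])})
    return pd.DataFrame(rows)


SCENARIOS = ("default", "lagged-wind", "no-rain")


def scenario_truth(name: str = "default") -> SyntheticTruth:
    """Named study scenarios: immediate wind response, one-day lagged wind
    response, or a rain-free record."""
    if name == "default":
        return SyntheticTruth()
    if name == "lagged-wind":
        return SyntheticTruth(blooms=BloomModel(lag_days=1))
    if name == "no-rain":
        return SyntheticTruth(rain=RainModel(wet_prob=0.0))
    raise ValidationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def generate_scenario(
    name: str = "default",
    years: int = 2,
    seed: int = 7,
    start: str = "2015-01-01",
) -> dict:
    """Generate a full study scenario: met, daily, monthly program, truth and
    bloom ledger, all seed-deterministic."""
    truth = scenario_truth(name)
    n_days = int(round(years * 365.25))
    met = generate_met(truth, start, n_days, seed=seed)
    daily, ledger = generate_daily_chl(truth, met, seed=seed + 1)
    monthly = generate_monthly_program(daily, day_rule=15, seed=seed + 2)
    return {
        "truth": truth,
        "met": met,
        "daily": daily,
        "ledger": ledger,
        "monthly": monthly,
    }


def generate_driver_event(
    n_days: int = 25,
    beta: float = 8.0,
    lag: int = 0,
    target_r2: float = 0.6,
    seed: int = 0,
    start: str = "2015-07-01",
) -> tuple[pd.DataFrame, dict]:
    """A single synthetic event frame with a known wind driver.

    Chlorophyll is ``c0 + beta * wind_avg(t - lag)`` plus centered lognormal
    noise scaled so the expected coefficient of determination is near
    ``target_r2`` — the regime where a daily-resolution driver model is
    informative but not trivial.  Returns the frame (chlorophyll plus all
    candidate predictor columns) and the ground truth.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValidationError("target_r2 must lie in (0, 1)")
    truth = SyntheticTruth(blooms=None)
    met = generate_met(truth, start, n_days + 1, seed=seed)
    rng = np.random.default_rng(seed + 1)

    dates = met.data.index[1:]  # drop day -1, kept only to supply the lag
    wind = met.data["wind_avg"]
    driver = wind.shift(lag).reindex(dates).to_numpy()

    signal = beta * driver
    signal_sd = float(np.std(signal, ddof=1))
    noise_sd = signal_sd * np.sqrt((1.0 - target_r2) / target_r2)
    ln_sigma = 0.6
    raw = rng.lognormal(mean=0.0, sigma=ln_sigma, size=len(dates))
    raw_sd = np.sqrt((np.exp(ln_sigma**2) - 1.0) * np.exp(ln_sigma**2))
    noise = (raw - np.exp(ln_sigma**2 / 2.0)) * (noise_sd / raw_sd)

    c0 = 60.0
    chl = np.maximum(c0 + signal + noise, 1.0)

    tm = truth.temperature
    temp = _seasonal(dates.dayofyear.to_numpy(), tm.mean, tm.amplitude, tm.peak_doy)
    temp = temp + rng.normal(0.0, tm.noise_sd, len(dates))

    frame = pd.DataFrame(
        {
            "chlorophyll": chl,
            "wind_avg": wind.reindex(dates).to_numpy(),
            "wind_avg_lag1": wind.shift(1).reindex(dates).to_numpy(),
            "wind_max": met.data["wind_max"].reindex(dates).to_numpy(),
            "temperature": temp,
            "rain": met.data["rain"].reindex(dates).to_numpy(),
        },
        index=dates,
    )
    truth_info = {
        "beta": beta,
        "lag": lag,
        "true_term": "wind_avg_lag1" if lag == 1 else "wind_avg",
        "target_r2": target_r2,
        "noise_sd": float(noise_sd),
    }
    return frame, truth_info
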