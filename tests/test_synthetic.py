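"""The synthetic-data generator: seed determinism, planted structure, and the
statistical regimes the downstream analyses assume."""

import numpy as np
import pandas as pd
import pytest

from chlorovar import (
    BloomModel,
    PipelineConfig,
    PlantedBloom,
    SyntheticTruth,
    ValidationError,
    build_monthly_matrix,
    detect_blooms,
    fit_decomposition,
    generate_15min,
    generate_daily_chl,
    generate_driver_event,
    generate_met,
    generate_monthly_program,
    generate_scenario,
    to_daily,
)
from chlorovar.drivers import ccf_screen
from chlorovar.io import OMITTED
from chlorovar.synthetic import RainModel, WindModel


class TestGenerateMet:
    def test_deterministic_wind_without_noise(self):
        truth = SyntheticTruth(wind=WindModel(ar1=0.0, innovation_sd=0.0, gust_sd=0.0))
        met = generate_met(truth, "2015-01-01", 30, seed=1)
        doy = met.data.index.dayofyear.to_numpy()
        w = truth.wind
        mu = w.mean + w.seasonal_amplitude * np.cos(2 * np.pi * (doy - w.peak_doy) / 365.25)
        np.testing.assert_allclose(met.data["wind_avg"], mu)

    def test_dry_scenario_has_zero_rain(self):
        truth = SyntheticTruth(rain=RainModel(wet_prob=0.0))
        met = generate_met(truth, "2015-01-01", 120, seed=2)
        assert (met.data["rain"] == 0.0).all()

    def test_wind_max_dominates_wind_avg(self):
        met = generate_met(SyntheticTruth(), "2015-01-01", 365, seed=3)
        assert (met.data["wind_max"] >= met.data["wind_avg"]).all()

    def test_ar1_autocorrelation_recovered(self):
        truth = SyntheticTruth(wind=WindModel(seasonal_amplitude=0.0, ar1=0.6,
                                              mean=30.0))  # high mean: no floor
        met = generate_met(truth, "2015-01-01", 4000, seed=4)
        w = met.data["wind_avg"].to_numpy()
        z = w - w.mean()
        acf1 = float(np.dot(z[1:], z[:-1]) / np.dot(z, z))
        se = np.sqrt(1.0 / len(z))  # white-noise scale SE for the check
        assert abs(acf1 - 0.6) <= 3 * 2 * se

    def test_seed_determinism(self):
        a = generate_met(SyntheticTruth(), "2015-01-01", 100, seed=9)
        b = generate_met(SyntheticTruth(), "2015-01-01", 100, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestGenerateDailyChl:
    def test_noiseless_seasonal_product_recovered_by_decomposition(self):
        truth = SyntheticTruth(noise_sigma=0.0, blooms=None)
        met = generate_met(truth, "2014-01-01", 5 * 365, seed=1)
        daily, ledger = generate_daily_chl(truth, met, seed=2)
        assert ledger == []
        samples = generate_monthly_program(daily, day_rule=15)
        result = fit_decomposition(build_monthly_matrix(samples))
        y_true = np.asarray(truth.annual_factors)
        np.testing.assert_allclose(result.annual.to_numpy(), y_true, rtol=1e-9)
        np.testing.assert_allclose(
            result.monthly.to_numpy(), np.asarray(truth.monthly_factors), rtol=1e-9
        )
        np.testing.assert_allclose(result.residuals.dropna(how="all").to_numpy(), 1.0)

    def test_planted_kernel_fires_detector_and_matches_ledger(self):
        truth = SyntheticTruth(
            noise_sigma=0.0,
            blooms=None,
            planted_blooms=(PlantedBloom("2015-03-10", rel_amplitude=2.4,
                                         rise_days=2, fall_days=1),),
        )
        met = generate_met(truth, "2015-01-01", 120, seed=1)
        daily, ledger = generate_daily_chl(truth, met, seed=2)
        assert len(ledger) == 1
        assert ledger[0]["amplitude_ugl"] >= 50.0
        events = detect_blooms(daily, PipelineConfig())
        assert len(events) == 1
        assert events[0].peak_date == pd.Timestamp("2015-03-10")

    def test_wind_triggered_blooms_recovered_one_to_one(self):
        truth = SyntheticTruth(noise_sigma=0.0,
                               blooms=BloomModel(refractory_days=40))
        met = generate_met(truth, "2015-01-01", 400, seed=5)
        daily, ledger = generate_daily_chl(truth, met, seed=6)
        big = [e for e in ledger if e["amplitude_ugl"] >= 50.0]
        events = detect_blooms(daily, PipelineConfig())
        planted = {e["peak_date"] for e in big}
        detected = {e.peak_date for e in events}
        assert planted <= detected

    def test_distribution_right_skewed_and_positive(self):
        bundle = generate_scenario("default", years=2, seed=7)
        chl = bundle["daily"].chlorophyll()
        assert (chl > 0).all()
        assert chl.mean() > chl.median()

    def test_temperature_and_salinity_regimes(self):
        bundle = generate_scenario("default", years=2, seed=7)
        temp = bundle["daily"].data["temperature"]
        sal = bundle["daily"].data["salinity"]
        assert 5.0 < temp.min() and temp.max() < 35.0
        assert 8.0 <= sal.min() and sal.max() <= 46.0


class TestGenerate15Min:
    def test_zero_diel_zero_noise_roundtrip_exact(self):
        truth = SyntheticTruth(noise_sigma=0.0, blooms=None)
        met = generate_met(truth, "2015-06-01", 5, seed=1)
        daily, _ = generate_daily_chl(truth, met, seed=2)
        sonde = generate_15min(daily, diel_amplitude=0.0, noise_sd=0.0)
        redaily, _ = to_daily(sonde)
        np.testing.assert_allclose(
            redaily.chlorophyll().to_numpy(), daily.chlorophyll().to_numpy()
        )

    def test_diel_signal_removed_by_daily_average(self):
        # the sinusoid has zero mean over the 96-point day, so averaging
        # recovers the daily value even with a strong diel cycle
        truth = SyntheticTruth(noise_sigma=0.0, blooms=None)
        met = generate_met(truth, "2015-06-01", 4, seed=1)
        daily, _ = generate_daily_chl(truth, met, seed=2)
        sonde = generate_15min(daily, diel_amplitude=0.3)
        redaily, _ = to_daily(sonde)
        np.testing.assert_allclose(
            redaily.chlorophyll().to_numpy(),
            daily.chlorophyll().to_numpy(),
            rtol=1e-9,
        )

    def test_75_minute_gap_omits_day(self):
        truth = SyntheticTruth(noise_sigma=0.0, blooms=None)
        met = generate_met(truth, "2015-06-01", 3, seed=1)
        daily, _ = generate_daily_chl(truth, met, seed=2)
        sonde = generate_15min(daily, gap_spec=(("2015-06-02T10:00", 75),))
        redaily, _ = to_daily(sonde)
        assert redaily.provenance.loc["2015-06-02", "chlorophyll"] == OMITTED

    def test_60_minute_gap_retained_near_truth(self):
        truth = SyntheticTruth(noise_sigma=0.0, blooms=None)
        met = generate_met(truth, "2015-06-01", 3, seed=1)
        daily, _ = generate_daily_chl(truth, met, seed=2)
        sonde = generate_15min(daily, diel_amplitude=0.1,
                               gap_spec=(("2015-06-02T10:00", 60),))
        redaily, _ = to_daily(sonde)
        truth_val = daily.chlorophyll().loc["2015-06-02"]
        got = redaily.chlorophyll().loc["2015-06-02"]
        # interpolated segment distorts the diel mean by < 1 % of the value
        assert got == pytest.approx(truth_val, rel=0.01)

    def test_overlapping_gaps_rejected(self):
        truth = SyntheticTruth(noise_sigma=0.0, blooms=None)
        met = generate_met(truth, "2015-06-01", 2, seed=1)
        daily, _ = generate_daily_chl(truth, met, seed=2)
        with pytest.raises(ValidationError, match="overlapping"):
            generate_15min(daily, gap_spec=(("2015-06-01T10:00", 60),
                                            ("2015-06-01T10:30", 60)))


class TestMonthlyProgram:
    def _daily(self, years=5):
        truth = SyntheticTruth(blooms=None)
        met = generate_met(truth, "2014-01-01", int(years * 365.25), seed=1)
        daily, _ = generate_daily_chl(truth, met, seed=2)
        return daily

    def test_five_year_record_yields_60_samples(self):
        samples = generate_monthly_program(self._daily())
        assert len(samples) == 60

    def test_skipped_month_missing_from_matrix(self):
        samples = generate_monthly_program(self._daily(), skip=((2017, 1),))
        assert len(samples) == 59
        matrix = build_monthly_matrix(samples)
        assert np.isnan(matrix.values.loc[2017, 1])

    def test_random_day_rule_reproducible(self):
        daily = self._daily(years=2)
        a = generate_monthly_program(daily, day_rule="random", seed=3)
        b = generate_monthly_program(daily, day_rule="random", seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestDriverEventGenerator:
    def test_lagged_generator_passes_ccf_screen(self):
        # with a one-day lagged driver the CCF screen admits the lag-1 term
        # in nearly every replicate
        hits = 0
        for s in range(100):
            frame, truth = generate_driver_event(n_days=25, lag=1, seed=500 + s)
            out = ccf_screen(frame["chlorophyll"], frame["wind_avg"])
            hits += out["include_lag1"]
        assert hits >= 90

    def test_target_r2_calibration(self):
        # fitted adj. r2 of the true single-term model lands in the
        # informative range the driver analysis targets
        from chlorovar import backward_eliminate

        r2s = []
        for s in range(50):
            frame, truth = generate_driver_event(n_days=25, lag=0, seed=900 + s)
            fit = backward_eliminate(("wind_avg",), frame.dropna(), alpha=1.0)
            r2s.append(fit.adj_r2)
        assert 0.4 <= float(np.mean(r2s)) <= 0.8
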