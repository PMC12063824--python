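"""Driver-model selection: event frames, CCF screen, AICc enumeration,
collinearity pruning and backward elimination — against naive oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from chlorovar import (
    PipelineConfig,
    ValidationError,
    aicc,
    analyze_event,
    backward_eliminate,
    build_event_frame,
    ccf_screen,
    detect_blooms,
    enumerate_models,
    prune_collinear,
)
from chlorovar.drivers import EventFrame

from conftest import make_daily, make_met


def _bloom_setup(rain=0.0, met_days=None, n=40, seed=None):
    values = np.full(n, 20.0)
    values[n // 2] = 100.0
    daily = make_daily(values, start="2015-07-01")
    met = make_met(met_days if met_days is not None else n + 20,
                   start="2015-06-15", rain=rain, seed=seed)
    events = detect_blooms(daily, PipelineConfig())
    assert len(events) == 1
    return events[0], daily, met


# ---------------------------------------------------------------------------
# naive re-implementations used as independent oracles


def naive_aicc(rss, n, k):
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def naive_enumerate(df, response, candidates):
    out = []
    y = df[response].to_numpy()
    n = len(y)
    for size in range(len(candidates) + 1):
        for terms in itertools.combinations(candidates, size):
            k = len(terms) + 2
            if n - k - 1 < 1:
                continue
            X = np.column_stack([np.ones(n)] + [df[t].to_numpy() for t in terms])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            rss = float(((y - X @ beta) ** 2).sum())
            out.append((terms, naive_aicc(rss, n, k)))
    out.sort(key=lambda item: (item[1], len(item[0]), item[0]))
    return out


def naive_term_pvalues(df, response, terms):
    """Two-sided t-tests for slopes from first principles."""
    from scipy import stats

    y = df[response].to_numpy()
    n = len(y)
    X = np.column_stack([np.ones(n)] + [df[t].to_numpy() for t in terms])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = n - X.shape[1]
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    tvals = beta / np.sqrt(np.diag(cov))
    p = 2 * stats.t.sf(np.abs(tvals), dof)
    return dict(zip(["intercept"] + list(terms), p))


def random_frame(rng, n=None, p=None):
    n = n or int(rng.integers(10, 31))
    p = p or int(rng.integers(1, 5))
    cols = {f"x{i}": rng.normal(size=n) for i in range(p)}
    cols["chlorophyll"] = rng.normal(50, 10, size=n)
    return pd.DataFrame(cols), [f"x{i}" for i in range(p)]


# ---------------------------------------------------------------------------


class TestBuildEventFrame:
    def test_zero_rain_event_excludes_rain(self):
        event, daily, met = _bloom_setup(rain=0.0)
        frame = build_event_frame(event, daily, met)
        assert frame.analyzable
        assert "rain" not in frame.candidates
        assert "rain" in frame.dropped

    def test_incomplete_met_flags_not_analyzable(self):
        event, daily, _ = _bloom_setup()
        met = make_met(10, start="2015-06-15")  # stops before the window
        frame = build_event_frame(event, daily, met)
        assert not frame.analyzable
        assert "met coverage" in frame.reason
        _, fit = analyze_event(event, daily, met)
        assert fit is None

    def test_lag_column_is_previous_day_met(self, rng):
        event, daily, met = _bloom_setup(seed=5)
        frame = build_event_frame(event, daily, met)
        for date in frame.data.index[1:]:
            prev = date - pd.Timedelta(days=1)
            assert frame.data.loc[date, "wind_avg_lag1"] == pytest.approx(
                met.data.loc[prev, "wind_avg"]
            )


class TestCcfScreen:
    def test_perfect_lagged_dependence_included(self):
        idx = pd.date_range("2015-07-01", periods=20, freq="D")
        rng = np.random.default_rng(1)
        wind = pd.Series(rng.normal(5, 2, 20), index=idx)
        chl = 2.0 * wind.shift(1, freq="D").reindex(idx)
        out = ccf_screen(chl, wind)
        assert out["include_lag1"]
        assert out["r_lag1"] == pytest.approx(1.0)

    def test_contemporaneous_only_dependence_excluded(self):
        # chl tracks wind with no lag; white-noise wind has no day-1 memory
        idx = pd.date_range("2015-07-01", periods=40, freq="D")
        rng = np.random.default_rng(2)
        wind = pd.Series(rng.normal(5, 2, 40), index=idx)
        chl = 1.0 * wind
        out = ccf_screen(chl, wind)
        assert out["r_lag0"] == pytest.approx(1.0)
        assert not out["include_lag1"]

    def test_white_noise_inclusion_near_nominal_level(self):
        # the 1.96/sqrt(n) band admits independent noise ~5% of the time
        rng = np.random.default_rng(3)
        idx = pd.date_range("2015-07-01", periods=20, freq="D")
        hits = 0
        n_sims = 1000
        for _ in range(n_sims):
            chl = pd.Series(rng.normal(size=20), index=idx)
            wind = pd.Series(rng.normal(size=20), index=idx)
            hits += ccf_screen(chl, wind)["include_lag1"]
        rate = hits / n_sims
        # nominal 5% with finite-n inflation; 3 binomial SEs around 0.05 plus
        # slack for the normal-approximation bound at n = 19
        assert 0.01 <= rate <= 0.11

    def test_constant_input_excluded_with_warning(self, caplog):
        idx = pd.date_range("2015-07-01", periods=10, freq="D")
        chl = pd.Series(np.arange(10.0), index=idx)
        wind = pd.Series(5.0, index=idx)
        out = ccf_screen(chl, wind)
        assert not out["include_lag1"]

    def test_too_few_pairs_rejected(self):
        idx = pd.date_range("2015-07-01", periods=4, freq="D")
        with pytest.raises(ValidationError):
            ccf_screen(pd.Series(1.0 * np.arange(4), index=idx),
                       pd.Series(np.arange(4.0), index=idx))


class TestAicc:
    def test_correction_term_arithmetic(self):
        # n=10, k=3: correction 2*3*4/6 = 4 on top of AIC
        rss, n, k = 5.0, 10, 3
        aic = n * math.log(rss / n) + 2 * k
        assert aicc(rss, n, k) == pytest.approx(aic + 4.0)

    def test_halving_rss_drops_n_ln2(self):
        assert aicc(10.0, 20, 3) - aicc(5.0, 20, 3) == pytest.approx(20 * math.log(2))

    def test_converges_to_aic_for_large_n(self):
        n, k, rss = 10**5, 3, 123.0
        aic = n * math.log(rss / n) + 2 * k
        assert aicc(rss, n, k) - aic == pytest.approx(0.0, abs=1e-3)

    def test_undefined_when_dof_exhausted(self):
        with pytest.raises(ValidationError):
            aicc(1.0, 5, 4)


class TestEnumerateModels:
    def test_two_candidates_four_models(self, rng):
        df, cands = random_frame(rng, n=20, p=2)
        assert len(enumerate_models(df, candidates=cands)) == 4

    def test_exact_fit_wins(self, rng):
        n = 15
        x1 = rng.normal(size=n)
        df = pd.DataFrame({"x1": x1, "x2": rng.normal(size=n), "chlorophyll": 3.0 * x1})
        ranked = enumerate_models(df, candidates=["x1", "x2"])
        assert ranked[0][0] == ("x1",)
        fit = backward_eliminate(("x1",), df)
        assert fit.coefficients["x1"] == pytest.approx(3.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_ranking_matches_naive_oracle(self, rng):
        for _ in range(100):
            df, cands = random_frame(rng)
            got = enumerate_models(df, candidates=cands)
            want = naive_enumerate(df, "chlorophyll", cands)
            assert [t for t, _ in got] == [t for t, _ in want]
            np.testing.assert_allclose(
                [a for _, a in got], [a for _, a in want], rtol=1e-9
            )

    def test_combinatorial_guard(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 14)),
                          columns=[f"x{i}" for i in range(13)] + ["chlorophyll"])
        with pytest.raises(ValidationError, match="refusing"):
            enumerate_models(df, candidates=[f"x{i}" for i in range(13)])


class TestPruneCollinear:
    def test_weaker_member_of_collinear_pair_dropped(self, rng):
        # wind_avg and wind_max nearly collinear; chlorophyll follows wind_max
        n = 30
        wind_max = rng.normal(8, 2, n)
        wind_avg = wind_max / 1.4 + rng.normal(0, 0.2, n)
        df = pd.DataFrame({
            "wind_avg": wind_avg,
            "wind_max": wind_max,
            "chlorophyll": 5.0 * wind_max + rng.normal(0, 3, n),
        })
        kept = prune_collinear(df, candidates=["wind_avg", "wind_max"])
        assert kept == ["wind_max"]

    def test_orthogonal_predictors_unchanged(self, rng):
        df, cands = random_frame(rng, n=30, p=3)
        assert prune_collinear(df, candidates=cands) == cands

    def test_three_mutually_collinear_leave_one(self, rng):
        n = 30
        base = rng.normal(size=n)
        df = pd.DataFrame({
            "a": base + rng.normal(0, 0.05, n),
            "b": base + rng.normal(0, 0.05, n),
            "c": base + rng.normal(0, 0.05, n),
            "chlorophyll": 2 * base + rng.normal(0, 0.5, n),
        })
        kept = prune_collinear(df, candidates=["a", "b", "c"])
        assert len(kept) == 1
        # deterministic: repeated runs agree
        assert prune_collinear(df, candidates=["a", "b", "c"]) == kept


class TestBackwardEliminate:
    def test_null_predictor_removed(self, rng):
        n = 30
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)  # unrelated
        df = pd.DataFrame({"x1": x1, "x2": x2,
                           "chlorophyll": 4 * x1 + rng.normal(0, 1, n)})
        fit = backward_eliminate(("x1", "x2"), df, alpha=0.05)
        assert fit.terms == ("x1",)
        assert fit.significant

    def test_all_significant_model_is_fixed_point(self, rng):
        n = 40
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        df = pd.DataFrame({"x1": x1, "x2": x2,
                           "chlorophyll": 4 * x1 - 3 * x2 + rng.normal(0, 1, n)})
        fit = backward_eliminate(("x1", "x2"), df, alpha=0.05)
        assert set(fit.terms) == {"x1", "x2"}

    def test_pure_noise_yields_flagged_intercept_only(self, rng):
        df, cands = random_frame(rng, n=25, p=3)
        # chlorophyll independent of all candidates in random_frame
        fit = backward_eliminate(tuple(cands), df, alpha=0.05)
        if fit.terms:  # rare chance selection must still be significant
            assert all(fit.p_values[t] <= 0.05 for t in fit.terms)
        else:
            assert not fit.significant

    def test_pvalues_match_first_principles(self, rng):
        for _ in range(25):
            df, cands = random_frame(rng, n=20, p=3)
            fit = backward_eliminate(tuple(cands), df, alpha=1.0)  # no removal
            want = naive_term_pvalues(df, "chlorophyll", cands)
            for term in cands:
                assert fit.p_values[term] == pytest.approx(want[term], rel=1e-8)

    def test_final_model_always_all_significant(self, rng):
        for _ in range(50):
            df, cands = random_frame(rng)
            fit = backward_eliminate(tuple(cands), df, alpha=0.05)
            assert all(fit.p_values[t] <= 0.05 for t in fit.terms)
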