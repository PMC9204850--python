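"""Covariate engineering: sunrise windows, window means, pressure
differencing, the rain indicator, z-scaling and the collinearity screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gobblewx.weather import (CollinearityScreen, CovariateScaler, MissingDayError,
                              build_daily_covariates, daily_means, pressure_change,
                              prepare_covariates, rain_indicator, records_in_window,
                              sunrise_window, zscore)


def _records(times, **cols):
    n = len(times)
    base = {"temperature": np.full(n, 10.0), "humidity": np.full(n, 70.0),
            "wind": np.full(n, 5.0), "pressure": np.full(n, 1010.0),
            "precipitation": np.zeros(n)}
    base.update({k: np.asarray(v, dtype=float) for k, v in cols.items()})
    return pd.DataFrame({"timestamp": pd.to_datetime(times), **base})


def quarter_hours(day="2017-04-01"):
    return pd.date_range(day, periods=96, freq="15min")


class TestSunriseWindow:
    def test_aligned_sunrise(self):
        start, end = sunrise_window("2017-04-01 06:30")
        assert start == pd.Timestamp("2017-04-01 06:00")
        assert end == pd.Timestamp("2017-04-01 09:00")
        assert (end - start) == pd.Timedelta(minutes=180)

    def test_window_holds_exactly_12_aligned_steps(self):
        recs = _records(quarter_hours())
        sub = records_in_window(recs, sunrise_window("2017-04-01 06:30"))
        assert len(sub) == 12

    def test_unaligned_sunrise_selects_by_enumeration(self):
        # sunrise 06:07 -> [05:37, 08:37); brute-force membership check
        window = sunrise_window("2017-04-01 06:07")
        recs = _records(quarter_hours())
        sub = records_in_window(recs, window)
        expected = [t for t in quarter_hours() if window[0] <= t < window[1]]
        assert list(sub["timestamp"]) == expected
        assert len(expected) == 12


class TestDailyMeans:
    def test_constant_records(self):
        recs = _records(quarter_hours(), temperature=np.full(96, 10.0))
        got = daily_means(recs, sunrise_window("2017-04-01 06:30"))
        assert got["temp_mean"] == 10.0
        assert got["n_records"] == 12

    def test_simple_average(self):
        times = ["2017-04-01 06:00", "2017-04-01 06:15", "2017-04-01 06:30"]
        recs = _records(times, temperature=[8, 10, 12])
        got = daily_means(recs, sunrise_window("2017-04-01 06:30"))
        assert got["temp_mean"] == pytest.approx(10.0)

    def test_empty_window_flags_missing_day(self):
        recs = _records(["2017-04-01 12:00"])
        with pytest.raises(MissingDayError):
            daily_means(recs, sunrise_window("2017-04-01 06:30"))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-30, 45), min_size=1, max_size=12),
           st.randoms(use_true_random=False))
    def test_matches_brute_force_and_order_invariant(self, temps, rnd):
        times = list(quarter_hours())[24:24 + len(temps)]
        order = list(range(len(temps)))
        rnd.shuffle(order)
        recs = _records([times[i] for i in order],
                        temperature=[temps[i] for i in order])
        window = (times[0], times[-1] + pd.Timedelta(minutes=15))
        got = daily_means(recs, window)
        total = 0.0
        for t in temps:
            total += t
        assert got["temp_mean"] == pytest.approx(total / len(temps), abs=1e-12)


class TestPressureChange:
    def test_example(self):
        days = pd.date_range("2017-04-01", periods=3, freq="D")
        out = pressure_change(pd.Series([1010.0, 1013.0, 1008.0], index=days))
        assert np.isnan(out.iloc[0])
        assert out.iloc[1] == pytest.approx(3.0)
        assert out.iloc[2] == pytest.approx(-5.0)

    def test_constant_series_is_zero_after_first_day(self):
        days = pd.date_range("2017-04-01", periods=5, freq="D")
        out = pressure_change(pd.Series(1012.0, index=days))
        assert np.allclose(out.iloc[1:], 0.0)

    def test_linear_series_has_constant_differences(self):
        days = pd.date_range("2017-04-01", periods=6, freq="D")
        out = pressure_change(pd.Series(1000.0 + 0.5 * np.arange(6), index=days))
        assert np.allclose(out.iloc[1:], 0.5)

    def test_telescoping_reconstruction(self):
        days = pd.date_range("2017-04-01", periods=20, freq="D")
        rng = np.random.default_rng(3)
        means = pd.Series(1010 + rng.normal(0, 2, 20), index=days)
        out = pressure_change(means)
        rebuilt = means.iloc[0] + out.fillna(0).cumsum()
        assert np.allclose(rebuilt, means)

    def test_gap_in_days_flags_missing_across_gap(self):
        days = pd.to_datetime(["2017-04-01", "2017-04-02", "2017-04-04"])
        out = pressure_change(pd.Series([1010.0, 1011.0, 1015.0], index=days))
        assert out.iloc[1] == pytest.approx(1.0)
        assert np.isnan(out.iloc[2])  # difference may not span the gap


class TestRainIndicator:
    def test_dry_morning(self):
        recs = _records(quarter_hours())
        assert rain_indicator(recs, sunrise_window("2017-04-01 06:30")) == 0

    def test_single_wet_record(self):
        precip = np.zeros(96)
        precip[26] = 0.2  # 06:30, inside the window
        recs = _records(quarter_hours(), precipitation=precip)
        assert rain_indicator(recs, sunrise_window("2017-04-01 06:30")) == 1

    def test_trace_threshold(self):
        precip = np.zeros(96)
        precip[26] = 0.2
        recs = _records(quarter_hours(), precipitation=precip)
        window = sunrise_window("2017-04-01 06:30")
        assert rain_indicator(recs, window, threshold=0.25) == 0


class TestZscore:
    def test_example(self):
        out, mean, sd = zscore([1.0, 2.0, 3.0])
        assert np.allclose(out, [-1, 0, 1])  # sample SD of 1,2,3 is 1
        assert (mean, sd) == (2.0, 1.0)

    def test_constant_series_raises(self):
        with pytest.raises(ValueError):
            zscore([5.0, 5.0, 5.0])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=50, unique=True))
    def test_moments_and_idempotence(self, values):
        out, _, _ = zscore(values)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std(ddof=1) - 1.0) < 1e-9
        again, _, _ = zscore(out)
        assert np.allclose(again, out, atol=1e-9)

    def test_missing_entries_stay_missing(self):
        out, _, _ = zscore([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out.iloc[1]) and np.isfinite(out.iloc[0])


class TestCollinearityScreen:
    def test_identical_columns(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=200)})
        sc = CollinearityScreen().fit(df)
        assert sc.correlation_.loc["a", "b"] == pytest.approx(1.0)
        assert len(sc.dropped_) == 1 and sc.dropped_[0] in ("a", "b")
        assert "c" in sc.retained_

    def test_negated_column_flagged_by_absolute_rule(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        sc = CollinearityScreen().fit(pd.DataFrame({"a": a, "neg": -a}))
        assert sc.correlation_.loc["a", "neg"] == pytest.approx(-1.0)
        assert [p[:2] for p in sc.flagged_pairs_] == [("a", "neg")]
        assert len(sc.dropped_) == 1

    def test_independent_columns_survive(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.normal(size=(1000, 4)),
                          columns=["w", "x", "y", "z"])
        sc = CollinearityScreen(threshold=0.60).fit(df)
        assert sc.dropped_ == []
        assert sc.fit(df).transform(df).shape == df.shape

    def test_drop_rule_removes_most_connected(self):
        rng = np.random.default_rng(2)
        hub = rng.normal(size=500)
        df = pd.DataFrame({
            "x1": hub + rng.normal(0, 0.3, 500),
            "hub": hub,
            "x2": hub + rng.normal(0, 0.3, 500),
        })
        sc = CollinearityScreen().fit(df)
        assert "hub" in sc.dropped_  # largest mean |r| goes first

    def test_too_few_complete_pairs_flagged_unavailable(self):
        df = pd.DataFrame({"a": [1.0, np.nan, np.nan, 2.0],
                           "b": [np.nan, 1.0, 2.0, np.nan],
                           "c": [1.0, 2.0, 3.0, 4.0]})
        sc = CollinearityScreen().fit(df)
        assert ("a", "b") in sc.unavailable_pairs_


class TestBuildDailyCovariates:
    def _inputs(self, n_days=5, drop_day=None):
        days = pd.date_range("2017-04-01", periods=n_days, freq="D")
        frames = []
        rng = np.random.default_rng(5)
        for d in days:
            if drop_day is not None and d == days[drop_day]:
                continue
            times = pd.date_range(d, periods=96, freq="15min")
            frames.append(_records(times, temperature=rng.normal(15, 2, 96),
                                   humidity=rng.uniform(60, 90, 96),
                                   wind=rng.uniform(2, 12, 96),
                                   pressure=rng.normal(1011, 1, 96)))
        weather = pd.concat(frames, ignore_index=True)
        weather.insert(0, "site", "A")
        sunrise = pd.DataFrame({"site": "A", "date": days,
                                "sunrise": days + pd.Timedelta(hours=6, minutes=37)})
        return weather, sunrise

    def test_complete_days(self):
        weather, sunrise = self._inputs()
        daily = build_daily_covariates(weather, sunrise)
        assert len(daily) == 5
        assert not daily["missing"].any()
        assert daily["n_records"].eq(12).all()
        assert np.isnan(daily["pressure_change"].iloc[0])
        assert daily["pressure_change"].iloc[1:].notna().all()

    def test_missing_day_propagates_not_imputed(self):
        weather, sunrise = self._inputs(drop_day=2)
        daily = build_daily_covariates(weather, sunrise)
        assert daily["missing"].iloc[2]
        assert np.isnan(daily["temp_mean"].iloc[2])
        # pressure change undefined on the gap day AND the day after it
        assert np.isnan(daily["pressure_change"].iloc[2])
        assert np.isnan(daily["pressure_change"].iloc[3])
        n_model_days = daily["pressure_change"].notna().sum()
        assert n_model_days == 5 - 3  # first day + gap day + day after

    def test_scaled_columns_standardized_over_fitting_frame(self):
        weather, sunrise = self._inputs(n_days=8)
        covs, scaler = prepare_covariates(weather, sunrise)
        frame = covs.loc[covs["pressure_change"].notna()]
        for col in ("scaled_temp", "scaled_bp_change"):
            assert abs(frame[col].mean()) < 1e-9
            assert abs(frame[col].std(ddof=1) - 1.0) < 1e-9

    def test_scaler_constants_transform_new_data_identically(self):
        weather, sunrise = self._inputs(n_days=8)
        covs, scaler = prepare_covariates(weather, sunrise)
        again, _ = prepare_covariates(weather, sunrise, scaler=scaler)
        pd.testing.assert_frame_equal(covs, again)
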