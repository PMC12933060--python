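import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wetlandflux.ingest import (
    DielConversion,
    airborne_daily,
    daily_from_halfhourly,
    fit_midday_daily,
    grid_airborne,
    merge_observations,
    midday_to_daily_ch4,
    midday_to_daily_co2,
)


def _halfhourly(day_values, date="2021-06-01", gas="CO2", present=None):
    """Build a one-day half-hourly frame; `present` selects which of the 48
    slots actually carry a record."""
    times = pd.Timestamp(date) + pd.to_timedelta((np.arange(48) + 0.5) / 2, unit="h")
    present = np.ones(48, dtype=bool) if present is None else np.asarray(present)
    vals = np.asarray(day_values, dtype=float)
    return pd.DataFrame({
        "tower_id": "T0", "pixel_row": 0, "pixel_col": 0,
        "timestamp": times[present], "gas": gas, "flux": vals[present], "qc": 0,
    })


class TestDailyCoverageRule:
    def test_full_day_constant_value(self):
        out = daily_from_halfhourly(_halfhourly(np.full(48, 5.0)))
        assert len(out) == 1
        assert out.loc[0, "mean"] == 5.0
        assert out.loc[0, "sd"] == 0.0
        assert out.loc[0, "n"] == 48

    def test_38_of_48_is_dropped(self):
        present = np.zeros(48, dtype=bool)
        present[:38] = True  # 79.2% < 80%, strict rule drops it
        out = daily_from_halfhourly(_halfhourly(np.arange(48.0), present=present))
        assert out.empty

    def test_39_of_48_retained_with_hand_mean(self):
        present = np.zeros(48, dtype=bool)
        present[:39] = True
        vals = np.zeros(48)
        vals[:39] = np.arange(1, 40)
        out = daily_from_halfhourly(_halfhourly(vals, present=present))
        assert len(out) == 1
        assert out.loc[0, "mean"] == pytest.approx(20.0)  # mean of 1..39

    def test_empty_series_gives_empty_table(self):
        assert daily_from_halfhourly(pd.DataFrame(columns=["timestamp", "gas", "flux"])).empty

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 48), min_size=1, max_size=20), st.integers(0, 2**31 - 1))
    def test_survivors_match_counting_oracle(self, counts, seed):
        """Exactly the days with present/48 > 0.8 survive, for arbitrary gaps."""
        rng = np.random.default_rng(seed)
        frames = []
        for i, n_present in enumerate(counts):
            date = pd.Timestamp("2021-01-01") + pd.Timedelta(days=i)
            present = np.zeros(48, dtype=bool)
            present[rng.choice(48, size=n_present, replace=False)] = True
            frames.append(_halfhourly(rng.normal(size=48), date=date, present=present))
        out = daily_from_halfhourly(pd.concat(frames, ignore_index=True))
        expected = sum(1 for n in counts if n / 48 > 0.8)
        assert len(out) == expected


class TestDielFit:
    def test_exact_line_recovered_with_zero_se(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        conv = fit_midday_daily(np.column_stack([x, 0.5 * x + 1.0]))
        assert conv.a == pytest.approx(0.5, abs=1e-12)
        assert conv.b == pytest.approx(1.0, abs=1e-12)
        assert conv.se_a == pytest.approx(0.0, abs=1e-10)
        assert conv.se_b == pytest.approx(0.0, abs=1e-10)

    def test_hand_worked_four_points(self):
        conv = fit_midday_daily([(0, 1), (1, 2), (2, 2), (3, 4)])
        assert conv.a == pytest.approx(0.9)
        assert conv.b == pytest.approx(0.9)

    def test_too_few_or_degenerate_pairs_raise(self):
        with pytest.raises(ValueError):
            fit_midday_daily([(0, 1), (1, 2)])
        with pytest.raises(ValueError):
            fit_midday_daily([(1, 1), (1, 2), (1, 3)])


class TestAirborneGridding:
    def _samples(self, values, hour=11, row=0, col=0, date="2022-04-19", gas="CO2"):
        n = len(values)
        ts = pd.Timestamp(date) + pd.Timedelta(hours=hour) + pd.to_timedelta(
            np.arange(n), unit="s")
        return pd.DataFrame({"timestamp": ts, "pixel_row": row, "pixel_col": col,
                             "gas": gas, "flux": values})

    def test_pooled_stats_in_one_pixel(self):
        out = grid_airborne(self._samples([1, 2, 3, 4, 5]), (4, 4))
        assert len(out) == 1
        assert out.loc[0, "midday_mean"] == pytest.approx(3.0)
        assert out.loc[0, "sd"] == pytest.approx(np.sqrt(2.5))
        assert out.loc[0, "n"] == 5

    def test_samples_before_window_excluded(self):
        out = grid_airborne(self._samples([1, 2, 3], hour=9.5), (4, 4))
        assert out.empty

    def test_two_flights_same_pixel_day_pool_samples(self):
        a = self._samples([1.0, 2.0], hour=10)
        b = self._samples([3.0, 4.0, 5.0], hour=13)
        out = grid_airborne(pd.concat([a, b], ignore_index=True), (4, 4))
        # pooling oracle: stats over the union of samples, not mean-of-means
        assert len(out) == 1
        assert out.loc[0, "midday_mean"] == pytest.approx(np.mean([1, 2, 3, 4, 5]))
        assert out.loc[0, "sd"] == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))
        assert out.loc[0, "n"] == 5

    def test_off_grid_samples_skipped(self):
        out = grid_airborne(self._samples([1.0, 2.0], row=99), (4, 4))
        assert out.empty


class TestMiddayToDaily:
    def test_published_intercept_at_zero_midday_flux(self):
        y, se = midday_to_daily_co2(0.0, 0.0, DielConversion())
        assert y == pytest.approx(0.58)
        assert se == pytest.approx(0.01)

    def test_slope_plus_intercept_at_unit_flux(self):
        y, _ = midday_to_daily_co2(1.0, 0.0, DielConversion())
        assert y == pytest.approx(0.85)

    def test_hand_propagated_se(self):
        _, se = midday_to_daily_co2(2.0, 0.0, DielConversion())
        assert se == pytest.approx(np.sqrt(4 * 0.002**2 + 0.01**2), rel=1e-9)

    def test_midday_variance_propagates(self):
        _, se = midday_to_daily_co2(0.0, 4.0, DielConversion())
        assert se == pytest.approx(np.sqrt(0.01**2 + 0.27**2 * 4.0), rel=1e-9)

    @pytest.mark.parametrize("x", [40.0, 0.0, -5.0])
    def test_ch4_daily_equals_midday(self, x):
        assert midday_to_daily_ch4(x) == x


class TestMerge:
    def _obs(self, n, source):
        return pd.DataFrame({
            "pixel_row": 0, "pixel_col": np.arange(n), "date": pd.Timestamp("2021-01-01"),
            "gas": "CO2", "mean": 1.0, "sd": 0.1, "n": 5, "source": source,
        })

    def test_concatenation_counts(self):
        merged = merge_observations(self._obs(10, "tower"), self._obs(20, "airborne"))
        assert len(merged) == 30

    def test_same_pixel_date_both_sources_kept(self):
        merged = merge_observations(self._obs(1, "tower"), self._obs(1, "airborne"))
        assert len(merged) == 2
        assert set(merged["source"]) == {"tower", "airborne"}

    def test_empty_airborne_passthrough(self):
        tower = self._obs(5, "tower")
        merged = merge_observations(tower, pd.DataFrame())
        pd.testing.assert_frame_equal(merged, tower)

    def test_unknown_gas_rejected(self):
        bad = self._obs(1, "tower").assign(gas="N2O")
        with pytest.raises(ValueError, match="gas"):
            merge_observations(bad, pd.DataFrame())


def test_airborne_daily_applies_conversion_per_gas():
    gridded = pd.DataFrame({
        "pixel_row": [0, 0], "pixel_col": [0, 0],
        "date": pd.Timestamp("2022-04-19"), "gas": ["CO2", "CH4"],
        "midday_mean": [2.0, 40.0], "sd": [0.0, 3.0], "n": [5, 5],
    })
    out = airborne_daily(gridded, DielConversion())
    co2 = out[out["gas"] == "CO2"].iloc[0]
    ch4 = out[out["gas"] == "CH4"].iloc[0]
    assert co2["mean"] == pytest.approx(0.27 * 2.0 + 0.58)
    assert ch4["mean"] == pytest.approx(40.0)
    assert (out["source"] == "airborne").all()
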