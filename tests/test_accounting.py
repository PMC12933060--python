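import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wetlandflux.accounting import (
    AccountingConfig,
    aggregate_by_unit,
    co2eq,
    mann_kendall,
    mass_scale,
    multi_year_mean,
    offset_ratio,
    sens_slope,
    to_mass_flux,
    trend_map,
)


def brute_force_mk(x):
    """Pairwise enumeration oracle for S, tau and Sen's slope."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    s = 0
    slopes = []
    for i in range(n):
        for j in range(i + 1, n):
            s += np.sign(x[j] - x[i])
            slopes.append((x[j] - x[i]) / (j - i))
    n0 = n * (n - 1) / 2
    _, counts = np.unique(x, return_counts=True)
    t1 = sum(c * (c - 1) / 2 for c in counts if c > 1)
    if t1 > 0:
        denom = np.sqrt((n0 - t1) * n0)
        tau = s / denom if denom > 0 else 0.0
    else:
        tau = s / n0
    return s, tau, float(np.median(slopes))


class TestMassConversion:
    def test_one_umol_co2_per_m2_year(self):
        # 1e-6 mol * 44.01 g/mol * 3.1536e7 s = 1387.9 g
        assert to_mass_flux(1.0, "CO2", per_pixel=False) == pytest.approx(1387.9, abs=0.1)

    def test_one_nmol_ch4_per_pixel_year(self):
        # 1e-9 * 16.04 * 3.1536e7 * 2.5e5 m2 = 126.5 kg
        assert to_mass_flux(1.0, "CH4", per_pixel=True) == pytest.approx(126.5e3, rel=1e-3)

    def test_zero_flux_zero_mass_and_sign_preserved(self):
        assert to_mass_flux(0.0, "CO2") == 0.0
        assert to_mass_flux(-2.0, "CO2") == -2.0 * mass_scale("CO2")

    def test_config_positivity_enforced(self):
        with pytest.raises(ValueError):
            AccountingConfig(gwp_ch4=-1.0)


class TestCo2eq:
    def test_worked_example(self):
        assert co2eq(-10.0, 0.1) == pytest.approx(-7.3)

    def test_ch4_zero_is_identity(self):
        assert co2eq(-5.5, 0.0) == -5.5

    def test_printed_gwp_factor(self):
        # 0.21 Tg CH4 -> 5.67 MMT CO2eq at GWP-100 = 27.0
        assert co2eq(0.0, 0.21) == pytest.approx(5.67)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.floats(-100, 100) for _ in range(4)]))
    def test_exact_linearity(self, vals):
        a1, a2, b1, b2 = vals
        assert co2eq(a1 + a2, b1 + b2) == pytest.approx(
            co2eq(a1, b1) + co2eq(a2, b2), abs=1e-9)


class TestOffsetRatio:
    def test_half_offset(self):
        # CH4 worth 5 MMT CO2eq against 10 MMT uptake
        assert offset_ratio(5.0 / 27.0, -10.0) == pytest.approx(50.0)

    def test_zero_ch4(self):
        assert offset_ratio(0.0, -10.0) == 0.0

    def test_no_net_uptake_flagged(self):
        assert np.isnan(offset_ratio(1.0, 2.0))
        assert np.isnan(offset_ratio(1.0, 0.0))


class TestUnitAggregation:
    def test_single_member_additivity(self):
        grid = np.array([[1.0, 2.0]])
        units = np.array([[0, 0]])
        out = aggregate_by_unit(grid, units)
        assert out[0]["total"] == pytest.approx(3.0)

    def test_one_unit_equals_regional_total(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(6, 6))
        out = aggregate_by_unit(grid, np.zeros((6, 6), dtype=int))
        assert out[0]["total"] == pytest.approx(grid.sum())

    def test_partition_sums_to_regional_total(self):
        rng = np.random.default_rng(1)
        grid = rng.normal(size=(8, 8))
        units = (np.arange(64) % 5).reshape(8, 8)
        out = aggregate_by_unit(grid, units)
        assert sum(rec["total"] for rec in out.values()) == pytest.approx(
            grid.sum(), rel=1e-9)

    def test_member_stack_sd_preserves_spatial_covariance(self):
        # two members, each summed over the unit before the SD
        members = np.stack([np.full((2, 2), 1.0), np.full((2, 2), 3.0)])
        out = aggregate_by_unit(members, np.zeros((2, 2), dtype=int))
        assert out[0]["total"] == pytest.approx(8.0)
        assert out[0]["sd"] == pytest.approx(np.std([4.0, 12.0], ddof=1))


class TestMannKendall:
    def test_strictly_increasing(self):
        res = mann_kendall([1.0, 2.0, 3.0, 4.0])
        assert res.s == 6
        assert res.tau == pytest.approx(1.0)

    def test_constant_series(self):
        res = mann_kendall([2.0] * 5)
        assert res.s == 0
        assert res.tau == 0.0
        assert res.p_value == 1.0

    def test_hand_worked_series(self):
        res = mann_kendall([1.0, 3.0, 2.0, 5.0])
        assert res.s == 4
        assert res.tau == pytest.approx(2.0 / 3.0)
        assert res.sen_slope == pytest.approx(7.0 / 6.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mann_kendall([1.0, 2.0, 3.0])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-5, 5), min_size=4, max_size=12))
    def test_matches_pairwise_enumeration(self, vals):
        res = mann_kendall(vals)
        s, tau, sen = brute_force_mk(vals)
        assert res.s == s
        assert res.tau == pytest.approx(tau, abs=1e-12)
        assert res.sen_slope == pytest.approx(sen, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=12, unique=True))
    def test_tau_matches_scipy_kendalltau(self, vals):
        res = mann_kendall(vals)
        expected = stats.kendalltau(np.arange(len(vals)), vals).statistic
        assert res.tau == pytest.approx(expected, abs=1e-9)

    def test_scale_equivariance(self):
        x = np.array([0.3, 1.9, 0.7, 2.5, 2.1])
        a, b = mann_kendall(x), mann_kendall(4.0 * x)
        assert b.tau == pytest.approx(a.tau)
        assert b.sen_slope == pytest.approx(4.0 * a.sen_slope)


class TestSensSlope:
    def test_exact_line(self):
        assert sens_slope([1.0, 2.0, 3.0, 4.0]) == pytest.approx(1.0)

    def test_constant(self):
        assert sens_slope([2.0, 2.0, 2.0]) == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            sens_slope([1.0])


class TestTrendMap:
    def test_linear_stack_recovers_slope_everywhere(self):
        years = np.arange(5)
        c = 0.7
        stack = c * years[:, None, None] * np.ones((5, 3, 3))
        out = trend_map(stack)
        np.testing.assert_allclose(out["sen_slope"], c)
        np.testing.assert_allclose(out["tau"], 1.0)

    def test_ramp_addition_shifts_slopes_by_c(self):
        rng = np.random.default_rng(2)
        stack = rng.normal(size=(6, 4, 4))
        years = np.arange(6)
        ramp = 1.3 * years[:, None, None]
        a = trend_map(stack)
        b = trend_map(stack + ramp)
        np.testing.assert_allclose(b["sen_slope"], a["sen_slope"] + 1.3, atol=1e-9)

    def test_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(3)
        stack = rng.normal(size=(7, 3, 2))
        out = trend_map(stack)
        for r in range(3):
            for c in range(2):
                s, tau, sen = brute_force_mk(stack[:, r, c])
                assert out["tau"][r, c] == pytest.approx(tau, abs=1e-12)
                assert out["sen_slope"][r, c] == pytest.approx(sen, abs=1e-12)

    def test_too_few_layers_rejected(self):
        with pytest.raises(ValueError):
            trend_map(np.zeros((3, 2, 2)))


class TestMultiYearMean:
    def test_single_year_identity(self):
        grid = np.arange(4.0).reshape(1, 2, 2)
        np.testing.assert_allclose(multi_year_mean(grid), grid[0])

    def test_constant_stack(self):
        stack = np.full((5, 2, 2), 3.3)
        np.testing.assert_allclose(multi_year_mean(stack), 3.3)

    def test_matches_hand_average(self):
        rng = np.random.default_rng(4)
        stack = rng.normal(size=(5, 3, 3))
        np.testing.assert_allclose(multi_year_mean(stack), stack.mean(axis=0))
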