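import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mowsense import (FieldSeries, Observation, SeasonWindow, SmoothingConfig,
                      ema_smooth, filter_ndvi_outliers, interpolate_daily,
                      moving_average_smooth, ndvi_from_bands)

D0 = dt.date(2018, 4, 1)


def _ndvi_series(day_value_pairs, field_id="A"):
    obs = [Observation(D0 + dt.timedelta(days=d), ndvi=v) for d, v in day_value_pairs]
    return FieldSeries(field_id, obs)


class TestNdviFromBands:
    @pytest.mark.parametrize("b4,b8,expected", [
        (0.2, 0.2, 0.0),
        (0.0, 0.5, 1.0),
        (0.1, 0.3, 0.5),
    ])
    def test_examples(self, b4, b8, expected):
        assert ndvi_from_bands(b4, b8) == pytest.approx(expected)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            ndvi_from_bands(0.0, 0.0)


class TestOutlierFilter:
    def test_cloud_mask_outlier_removed_within_ten_days(self):
        # curvature 0.75 - 2*0.38 + 0.78 = 0.77 >= 0.6
        series = _ndvi_series([(0, 0.75), (4, 0.38), (8, 0.78)])
        cleaned, removed = filter_ndvi_outliers(series)
        assert removed == [1]
        assert [o.ndvi for o in cleaned.observations] == [0.75, 0.78]

    def test_same_triplet_spanning_twelve_days_is_kept(self):
        series = _ndvi_series([(0, 0.75), (6, 0.38), (12, 0.78)])
        cleaned, removed = filter_ndvi_outliers(series)
        assert removed == [] and len(cleaned) == 3

    def test_constant_series_untouched(self):
        series = _ndvi_series([(0, 0.5), (3, 0.5), (6, 0.5)])
        _, removed = filter_ndvi_outliers(series)
        assert removed == []

    def test_fewer_than_three_valid_returned_unchanged(self):
        series = _ndvi_series([(0, 0.1), (3, 0.9)])
        cleaned, removed = filter_ndvi_outliers(series)
        assert cleaned is series and removed == []

    def test_coherence_on_outlier_date_survives(self):
        obs = [
            Observation(D0, ndvi=0.75),
            Observation(D0 + dt.timedelta(days=4), ndvi=0.05, cohvv=0.3, cohvh=0.2),
            Observation(D0 + dt.timedelta(days=8), ndvi=0.78),
        ]
        cleaned, removed = filter_ndvi_outliers(FieldSeries("A", obs))
        assert removed == [1]
        middle = cleaned.observations[1]
        assert middle.ndvi is None and middle.cohvv == 0.3

    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_keeps_endpoints(self, values):
        # 4-day cadence: a removal widens surviving triplets past the
        # 10-day guard, so a second pass can never flag anything new
        series = _ndvi_series([(4 * i, v) for i, v in enumerate(values)])
        cleaned, removed = filter_ndvi_outliers(series)
        assert 0 not in removed and len(values) - 1 not in removed
        again, removed2 = filter_ndvi_outliers(cleaned)
        assert removed2 == []


class TestEma:
    def test_alpha_one_is_identity(self):
        x = np.array([0.1, 0.9, 0.4])
        np.testing.assert_array_equal(ema_smooth(x, 1.0), x)

    def test_constant_fixed_point(self):
        np.testing.assert_allclose(ema_smooth(np.full(10, 0.3), 0.2), np.full(10, 0.3))

    def test_two_point_closed_form(self):
        out = ema_smooth([0.2, 0.4], 1 / 3)
        np.testing.assert_allclose(out, [0.2, 0.2 + (0.4 - 0.2) / 3])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ema_smooth([], 0.5)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
           st.floats(0.05, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_recursion_matches_weighted_sum_expansion(self, values, alpha):
        """out_n = sum_k alpha(1-alpha)^k in_{n-k} + (1-alpha)^(n-1) in_1."""
        out = ema_smooth(values, alpha)
        for n in range(1, len(values) + 1):
            expected = (1 - alpha) ** (n - 1) * values[0]
            expected += sum(alpha * (1 - alpha) ** k * values[n - 1 - k]
                            for k in range(n - 1))
            assert out[n - 1] == pytest.approx(expected, abs=1e-10)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
           st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_stays_within_input_range(self, values, alpha):
        out = ema_smooth(values, alpha)
        assert out.min() >= min(values) - 1e-12
        assert out.max() <= max(values) + 1e-12


class TestMovingAverage:
    def test_constant_fixed_point(self):
        np.testing.assert_allclose(moving_average_smooth(np.full(9, 0.4), 3),
                                   np.full(9, 0.4))

    def test_simple_window(self):
        out = moving_average_smooth([0.0, 1.0, 2.0], 3)
        assert out[1] == pytest.approx(1.0)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            moving_average_smooth([1.0, 2.0, 3.0], 4)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
           st.sampled_from([3, 5, 7]))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_truncated_window(self, values, width):
        out = moving_average_smooth(values, width)
        half = width // 2
        n = len(values)
        for i in range(n):
            h = min(half, i, n - 1 - i)
            expected = np.mean(values[i - h : i + h + 1])
            assert out[i] == pytest.approx(expected, abs=1e-12)


class TestInterpolateDaily:
    def test_linear_midpoint(self):
        series = _ndvi_series([(0, 0.2), (2, 0.4)])
        grid = interpolate_daily(series, SeasonWindow())
        assert grid.ndvi[1] == pytest.approx(0.3)

    def test_single_measurement_held_constant(self):
        series = _ndvi_series([(100, 0.5)])
        grid = interpolate_daily(series, SeasonWindow())
        np.testing.assert_allclose(grid.ndvi, 0.5)

    def test_shape_contract_and_no_missing(self, small_dataset):
        cfg, series, _, _ = small_dataset
        grid = interpolate_daily(series[0], cfg.window)
        for name in ("ndvi", "cohvv", "cohvh", "cohvv_sm", "cohvh_sm"):
            arr = getattr(grid, name)
            assert arr.shape == (215,) and np.all(np.isfinite(arr))

    def test_measurement_days_reproduce_raw_values(self):
        pairs = [(5, 0.2), (30, 0.8), (77, 0.4)]
        series = _ndvi_series(pairs)
        grid = interpolate_daily(series, SeasonWindow())
        for d, v in pairs:
            assert grid.ndvi[d] == pytest.approx(v)
            assert grid.ndvi_valid[d]
        assert grid.ndvi_valid.sum() == len(pairs)

    def test_smoothing_applied_before_interpolation(self):
        obs = [Observation(D0 + dt.timedelta(days=d), cohvv=v, cohvh=v)
               for d, v in [(0, 0.2), (6, 0.8), (12, 0.2)]]
        series = FieldSeries("A", obs)
        grid = interpolate_daily(series, SeasonWindow(),
                                 SmoothingConfig(method="ema", alpha=1 / 3))
        expected = ema_smooth([0.2, 0.8, 0.2], 1 / 3)
        assert grid.cohvv_sm[6] == pytest.approx(expected[1])
        assert grid.cohvv_sm[12] == pytest.approx(expected[2])

    def test_smoothed_coherence_within_unit_interval(self, small_grids):
        for g in small_grids:
            assert g.cohvv_sm.min() >= 0.0 and g.cohvv_sm.max() <= 1.0
            assert g.cohvh_sm.min() >= 0.0 and g.cohvh_sm.max() <= 1.0
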