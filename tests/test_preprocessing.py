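"""Cleaning chain: 3-sigma flagging, repair, scaling, Savitzky-Golay smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from barncast.preprocessing import (
    NormalizationParams,
    OutlierPolicy,
    RawSeries,
    SmoothingParams,
    denormalize,
    detect_outliers,
    minmax_normalize,
    replace_outliers,
    savgol_smooth,
)
from conftest import make_series


class TestDetectOutliers:
    def test_constant_channel_has_no_flags(self):
        series = make_series({"x": [5, 5, 5, 5]})
        mask = detect_outliers(series)
        assert not mask["x"].any()

    def test_flags_injected_spike_and_matches_residual_recomputation(self):
        rng = np.random.default_rng(42)
        vals = rng.standard_normal(100)
        vals[42] = 10.0
        series = make_series({"x": vals})
        mask = detect_outliers(series)
        # independent recomputation of the rule
        sigma = vals.std(ddof=0)
        expected = np.abs(vals - vals.mean()) > 3.0 * sigma
        assert mask["x"].to_numpy()[42]
        np.testing.assert_array_equal(mask["x"].to_numpy(), expected)

    def test_single_extreme_point_hand_arithmetic(self):
        # values [0]*9 + [100]: mean 10, population sigma 30, residual 90 = 3*sigma
        # exactly, so the strict > comparison does NOT flag it
        series = make_series({"x": [0] * 9 + [100]})
        mask = detect_outliers(series)
        assert not mask["x"].any()
        # a tighter multiplier does flag it
        mask2 = detect_outliers(series, OutlierPolicy(sigma_multiplier=2.9))
        assert mask2["x"].to_numpy()[9] and mask2["x"].sum() == 1

    def test_mask_invariant_under_affine_rescaling(self, rng):
        vals = rng.standard_normal(200)
        vals[17] = 8.0
        a = make_series({"x": vals})
        b = make_series({"x": 3.5 * vals - 40.0})
        pd.testing.assert_frame_equal(detect_outliers(a), detect_outliers(b))

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            detect_outliers(make_series({"x": [1.0]}))


class TestReplaceOutliers:
    def test_empty_mask_is_identity(self, small_series):
        mask = small_series.frame.astype(bool) & False
        out = replace_outliers(small_series, mask)
        pd.testing.assert_frame_equal(out.frame, small_series.frame)

    def test_linear_interpolation_of_interior_point(self):
        series = make_series({"x": [1, 100, 3]})
        mask = series.frame == 100
        out = replace_outliers(series, mask)
        np.testing.assert_allclose(out.frame["x"].to_numpy(), [1, 2, 3])

    def test_boundary_falls_back_to_nearest_clean_value(self):
        series = make_series({"x": [100, 2, 3]})
        mask = series.frame == 100
        out = replace_outliers(series, mask)
        np.testing.assert_allclose(out.frame["x"].to_numpy(), [2, 2, 3])

    def test_previous_value_policy(self):
        series = make_series({"x": [1, 100, 3]})
        mask = series.frame == 100
        out = replace_outliers(series, mask, OutlierPolicy(replacement="previous-value"))
        np.testing.assert_allclose(out.frame["x"].to_numpy(), [1, 1, 3])

    def test_unflagged_points_bit_identical_and_no_gaps(self, rng):
        vals = rng.standard_normal(50)
        series = make_series({"x": vals})
        mask = detect_outliers(series, OutlierPolicy(sigma_multiplier=1.0))
        out = replace_outliers(series, mask)
        keep = ~mask["x"].to_numpy()
        np.testing.assert_array_equal(out.frame["x"].to_numpy()[keep], vals[keep])
        assert out.frame.notna().all().all()
        assert len(out) == len(series)


class TestMinMax:
    def test_direct_evaluation(self):
        series = make_series({"x": [0, 5, 10]})
        normed, _ = minmax_normalize(series)
        np.testing.assert_allclose(normed.frame["x"].to_numpy(), [0.0, 0.5, 1.0])

    def test_output_spans_unit_interval(self, rng):
        series = make_series({"x": rng.uniform(-50, 90, size=64)})
        normed, _ = minmax_normalize(series)
        assert normed.frame["x"].min() == 0.0
        assert normed.frame["x"].max() == 1.0
        assert ((normed.frame >= 0) & (normed.frame <= 1)).all().all()

    def test_degenerate_channel_maps_to_zero(self):
        normed, params = minmax_normalize(make_series({"x": [7, 7, 7]}))
        np.testing.assert_array_equal(normed.frame["x"].to_numpy(), [0, 0, 0])
        # and the round trip recovers the constant
        back = denormalize(normed, params)
        np.testing.assert_array_equal(back.frame["x"].to_numpy(), [7, 7, 7])

    def test_round_trip_identity(self, rng):
        series = make_series({"x": rng.uniform(3, 900, size=1000)})
        normed, params = minmax_normalize(series)
        back = denormalize(normed, params)
        np.testing.assert_allclose(back.frame.to_numpy(), series.frame.to_numpy(), rtol=1e-12)

    def test_known_params_inverse_map(self):
        params = NormalizationParams(pd.Series({"x": 0.0}), pd.Series({"x": 10.0}))
        series = make_series({"x": [0.0, 0.5, 1.0]})
        back = denormalize(series, params)
        np.testing.assert_allclose(back.frame["x"].to_numpy(), [0, 5, 10])

    def test_params_file_round_trip(self, tmp_path, rng):
        series = make_series({"a": rng.uniform(0, 1, 10), "b": rng.uniform(-5, 5, 10)})
        _, params = minmax_normalize(series)
        path = tmp_path / "scaling.txt"
        params.to_file(path)
        loaded = NormalizationParams.from_file(path)
        pd.testing.assert_series_equal(loaded.x_min, params.x_min)
        pd.testing.assert_series_equal(loaded.x_max, params.x_max)


class TestProperties:
    """Invariants over arbitrary channel data."""

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        vals=hnp.arrays(np.float64, st.integers(5, 60),
                        elements=st.floats(-1e3, 1e3, allow_nan=False)),
        scale=st.floats(0.01, 100.0),
        shift=st.floats(-1e3, 1e3),
    )
    def test_outlier_mask_affine_invariant_and_normalization_bounded(self, vals, scale, shift):
        series = make_series({"x": vals})
        rescaled = make_series({"x": scale * vals + shift})
        pd.testing.assert_frame_equal(detect_outliers(series), detect_outliers(rescaled))
        normed, params = minmax_normalize(series)
        assert ((normed.frame >= 0) & (normed.frame <= 1)).all().all()
        back = denormalize(normed, params)
        np.testing.assert_allclose(back.frame["x"].to_numpy(), vals, atol=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        vals=hnp.arrays(np.float64, st.integers(2, 40),
                        elements=st.floats(-1e6, 1e6, allow_nan=False)),
        multiplier=st.floats(0.5, 5.0),
    )
    def test_replacement_touches_exactly_the_flagged_points(self, vals, multiplier):
        series = make_series({"x": vals})
        mask = detect_outliers(series, OutlierPolicy(sigma_multiplier=multiplier))
        out = replace_outliers(series, mask, OutlierPolicy(sigma_multiplier=multiplier))
        keep = ~mask["x"].to_numpy()
        np.testing.assert_array_equal(out.frame["x"].to_numpy()[keep], vals[keep])
        assert out.frame.notna().all().all()


class TestSavgol:
    def test_reproduces_cubic_exactly(self):
        t = np.arange(21, dtype=float)
        series = make_series({"x": 2 * t**3 - t + 1})
        out = savgol_smooth(series, SmoothingParams(7, 3))
        np.testing.assert_allclose(out.frame["x"].to_numpy(), series.frame["x"].to_numpy(),
                                   atol=1e-9)

    def test_constant_unchanged(self):
        series = make_series({"x": np.full(30, 4.2)})
        out = savgol_smooth(series, SmoothingParams(11, 2))
        np.testing.assert_allclose(out.frame["x"].to_numpy(), 4.2)

    def test_order_zero_equals_moving_average(self, rng):
        vals = rng.standard_normal(40)
        series = make_series({"x": vals})
        out = savgol_smooth(series, SmoothingParams(5, 0))
        # windowed-mean oracle on interior points
        expected = np.convolve(vals, np.ones(5) / 5, mode="valid")
        np.testing.assert_allclose(out.frame["x"].to_numpy()[2:-2], expected, atol=1e-12)

    def test_linearity(self, rng):
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        a, b = 2.5, -1.25
        params = SmoothingParams(9, 2)
        sx = savgol_smooth(make_series({"c": x}), params).frame["c"].to_numpy()
        sy = savgol_smooth(make_series({"c": y}), params).frame["c"].to_numpy()
        sxy = savgol_smooth(make_series({"c": a * x + b * y}), params).frame["c"].to_numpy()
        np.testing.assert_allclose(sxy, a * sx + b * sy, atol=1e-9)

    def test_window_longer_than_series_errors(self):
        with pytest.raises(ValueError):
            savgol_smooth(make_series({"x": [1, 2, 3]}), SmoothingParams(5, 1))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SmoothingParams(4, 1)  # even window
        with pytest.raises(ValueError):
            SmoothingParams(5, 5)  # order >= window
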