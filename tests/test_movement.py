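"""Movement intensity, smoothing, resampling and cross-covariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupcall.movement import (MovementTrace, RateVector, bin_usv_rate,
                              matched_shuffled, movement_intensity, pooled_cc,
                              resample_to_rate_base, smooth_trace, xcov_coeff)


def brute_xcov(a, b, max_lag_bins):
    """O(n^2) definition of the coefficient-scaled cross-covariance."""
    da, db = a - a.mean(), b - b.mean()
    norm = np.sqrt((da @ da) * (db @ db))
    out = []
    for lag in range(-max_lag_bins, max_lag_bins + 1):
        s = sum(da[t] * db[t + lag] for t in range(len(a)) if 0 <= t + lag < len(b))
        out.append(s / norm)
    return np.array(out)


def _blob_stack(n_frames=6, size=64, speed=1, blob_r=6):
    """Gaussian blob translating rightward at `speed` px/frame, with masks."""
    yy, xx = np.mgrid[0:size, 0:size]
    frames, masks = [], []
    for i in range(n_frames):
        cx = 15 + i * speed
        blob = np.exp(-(((xx - cx) ** 2 + (yy - size // 2) ** 2) / (2 * blob_r ** 2)))
        frames.append(blob)
        masks.append(blob > 0.05)
    return np.array(frames), np.array(masks)


class TestMovementIntensity:
    def test_static_frames_zero_trace(self):
        frames = np.ones((5, 32, 32))
        masks = np.ones((5, 32, 32), dtype=bool)
        for method in ("flow", "framediff"):
            tr = movement_intensity(frames, masks, method=method)
            assert np.allclose(tr.intensity, 0.0, atol=1e-6)

    @pytest.mark.parametrize("method", ["flow", "framediff"])
    def test_double_speed_doubles_intensity(self, method):
        f1, m1 = _blob_stack(speed=1)
        f2, m2 = _blob_stack(speed=2)
        i1 = movement_intensity(f1, m1, method=method).intensity[1:].mean()
        i2 = movement_intensity(f2, m2, method=method).intensity[1:].mean()
        assert i2 / i1 == pytest.approx(2.0, rel=0.3)

    def test_mask_excluding_motion_gives_zero(self):
        frames, _ = _blob_stack()
        masks = np.zeros_like(frames, dtype=bool)
        masks[:, :4, :4] = True  # static corner only
        tr = movement_intensity(frames, masks, method="framediff")
        # only the far Gaussian tail leaks into the static corner
        assert np.allclose(tr.intensity, 0.0, atol=1e-4)

    def test_empty_mask_warns_and_zeroes(self):
        frames, masks = _blob_stack()
        masks[3] = False
        with pytest.warns(UserWarning, match="empty mask"):
            tr = movement_intensity(frames, masks, method="framediff")
        assert tr.intensity[3] == 0.0

    def test_first_frame_duplicates_second(self):
        frames, masks = _blob_stack()
        tr = movement_intensity(frames, masks, method="framediff")
        assert tr.intensity[0] == tr.intensity[1]
        assert len(tr.intensity) == len(frames)


class TestSmoothTrace:
    def test_constant_unchanged(self):
        tr = smooth_trace(MovementTrace(np.full(200, 3.0), 30.0), 90)
        assert np.allclose(tr.intensity, 3.0)
        assert tr.smoothed

    def test_unit_impulse_span_three(self):
        x = np.zeros(9)
        x[4] = 1.0
        sm = smooth_trace(MovementTrace(x, 30.0), 3).intensity
        assert np.allclose(sm[3:6], 1 / 3)
        assert np.allclose(sm[:3], 0) and np.allclose(sm[6:], 0)

    def test_noise_variance_reduced_by_span(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100_000)
        sm = smooth_trace(MovementTrace(x, 30.0), 90).intensity
        assert sm.var() == pytest.approx(1 / 90, rel=0.15)

    def test_span_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(MovementTrace(np.zeros(10), 30.0), 20)


class TestResample:
    def test_session_bin_arithmetic(self):
        rv = bin_usv_rate([], 300.0, 3.0)
        assert len(rv.counts) == 100
        tr = MovementTrace(np.zeros(9000), 30.0)
        assert len(resample_to_rate_base(tr, rv)) == 100

    def test_linear_ramp_exact_at_centers(self):
        tr = MovementTrace(np.arange(9000, dtype=float), 30.0)
        rv = bin_usv_rate([], 300.0, 3.0)
        out = resample_to_rate_base(tr, rv)
        # ramp slope is 30 units/s; centers at 1.5, 4.5, ... seconds
        expected = rv.bin_centers_s * 30.0 - 0.5
        assert np.allclose(out, expected)

    def test_coverage_gap_rejected(self):
        tr = MovementTrace(np.zeros(300), 30.0)  # only 10 s of frames
        rv = bin_usv_rate([], 300.0, 3.0)
        with pytest.raises(ValueError, match="cover"):
            resample_to_rate_base(tr, rv)

    def test_rate_vector_totals_match_onsets(self):
        rng = np.random.default_rng(2)
        onsets = rng.uniform(0, 300, size=137)
        rv = bin_usv_rate(onsets, 300.0, 3.0)
        assert rv.counts.sum() == 137
        assert np.issubdtype(rv.counts.dtype, np.integer)


class TestXcov:
    def test_self_xcov_at_lag_zero_is_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(50)
        lags, curve = xcov_coeff(a, a, max_lag_s=0.0)
        assert lags.tolist() == [0.0]
        assert curve[0] == pytest.approx(1.0, abs=1e-12)

    def test_shift_property(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(200)
        b = np.roll(a, 4)  # b follows a by 4 bins
        lags, curve = xcov_coeff(a, b, max_lag_s=30.0, bin_width_s=3.0)
        assert lags[np.argmax(curve)] == pytest.approx(12.0)

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(10, 200))
    def test_matches_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        lags, curve = xcov_coeff(a, b, max_lag_s=15.0, bin_width_s=3.0)
        assert np.abs(curve - brute_xcov(a, b, 5)).max() < 1e-10
        assert np.all(np.abs(curve) <= 1.0 + 1e-12)

    def test_symmetry_under_argument_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(80), rng.standard_normal(80)
        _, ab = xcov_coeff(a, b, 30.0)
        _, ba = xcov_coeff(b, a, 30.0)
        assert np.allclose(ab, ba[::-1], atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            xcov_coeff(np.ones(10), np.arange(10.0), 3.0)


class TestMatchedShuffled:
    def test_identical_movement_and_rate_gives_cc_one(self):
        rng = np.random.default_rng(5)
        x1, x2 = rng.standard_normal(100), rng.standard_normal(100)
        res = matched_shuffled(x1, x1, x2, x2)
        i0 = np.flatnonzero(res.lags_s == 0)[0]
        assert res.matched_curve[i0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_usv_session_excluded(self):
        rng = np.random.default_rng(6)
        mov = rng.standard_normal(100)
        zero_rate = np.zeros(100)
        assert matched_shuffled(mov, zero_rate, mov, rng.poisson(1, 100).astype(float)) is None


class TestPooledCc:
    lags = np.arange(-5, 6) * 3.0

    def test_single_trial_max_in_window(self):
        curve = np.linspace(-0.5, 0.5, 11)  # max at +15 s, outside window
        res = pooled_cc([curve], self.lags, window_s=5.0)
        in_win = np.abs(self.lags) <= 5.0
        assert res.pooled_cc == pytest.approx(curve[in_win].max())
        assert abs(res.pooled_lag_s) <= 5.0

    def test_flat_curves_give_zero(self):
        res = pooled_cc([np.zeros(11), np.zeros(11)], self.lags)
        assert res.pooled_cc == 0.0
        assert res.pooled_lag_s == 0.0  # tie resolves to the lag nearest 0

    def test_tie_breaks_toward_zero_lag(self):
        curve = np.zeros(11)
        curve[np.flatnonzero(self.lags == -3.0)[0]] = 0.4
        curve[np.flatnonzero(self.lags == 0.0)[0]] = 0.4
        res = pooled_cc([curve], self.lags)
        assert res.pooled_lag_s == 0.0

    def test_per_trial_ccs_read_at_pooled_lag(self):
        c1, c2 = np.zeros(11), np.zeros(11)
        idx = np.flatnonzero(self.lags == 3.0)[0]
        c1[idx], c2[idx] = 0.8, 0.2
        res = pooled_cc([c1, c2], self.lags)
        assert res.pooled_lag_s == 3.0
        assert res.per_trial_ccs.tolist() == [0.8, 0.2]
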