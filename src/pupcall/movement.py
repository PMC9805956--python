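"""Movement intensity vs. USV rate cross-covariance.

The analysis pairs a per-frame whole-body movement-intensity trace with
the session's USV rate (syllable counts in 3-s bins).  The movement trace
is smoothed with a 90-frame moving average (3 s at 30 fps) and linearly
interpolated onto the rate-vector time base; the two are compared with a
coefficient-scaled cross-covariance (mean-subtracted, normalized so each
vector's lag-0 auto-covariance is 1, bounding the curve in [-1, 1]).

A matched comparison pairs movement and USVs from the same 5-min session;
a shuffled comparison crosses the two sessions of a trial (isolation
movement vs. re-isolation USVs and vice versa), forming an empirical null
with the same marginal statistics.  Group-level covariance coefficients
(CCs) are read off the mean pooled matched curve at its peak within
|lag| <= 5 s; each trial's CC is the value of its own curve at that lag.

Sign convention: a positive lag means the second series follows the
first, so xcov(movement, rate) peaks at a positive lag when vocalization
lags movement.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import scipy.signal


@dataclass(frozen=True)
class MovementTrace:
    """Per-frame scalar movement intensity (arbitrary nonnegative units)."""

    intensity: np.ndarray
    frame_rate_hz: float
    smoothed: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("movement intensity must be finite")
        object.__setattr__(self, "intensity", arr)

    @property
    def times_s(self) -> np.ndarray:
        """Frame i spans [i, i+1)/rate; its intensity is stamped mid-frame."""
        return (np.arange(len(self.intensity)) + 0.5) / self.frame_rate_hz


@dataclass(frozen=True)
class RateVector:
    """USV counts per fixed-width time bin."""

    counts: np.ndarray
    bin_edges_s: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if len(self.bin_edges_s) != len(c) + 1:
            raise ValueError("need len(counts) + 1 bin edges")

    @property
    def bin_centers_s(self) -> np.ndarray:
        e = np.asarray(self.bin_edges_s, dtype=float)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def bin_width_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])


def bin_usv_rate(onsets_s, session_length_s: float, bin_width_s: float = 3.0) -> RateVector:
    """Count syllable onsets in fixed 3-s bins over the session."""
    n_bins = int(round(session_length_s / bin_width_s))
    edges = np.arange(n_bins + 1) * bin_width_s
    counts, _ = np.histogram(np.asarray(list(onsets_s), dtype=float), bins=edges)
    return RateVector(counts=counts.astype(np.int64), bin_edges_s=edges)


def movement_intensity(frames: np.ndarray, masks: np.ndarray,
                       frame_rate_hz: float = 30.0,
                       method: str = "flow") -> MovementTrace:
    """Per-frame movement intensity from a frame stack and binary body masks.

    ``method='flow'`` sums the dense optical-flow magnitude (iterative
    Lucas-Kanade) within the mask for each consecutive frame pair;
    ``method='framediff'`` sums the absolute intensity difference inside
    the mask — a cheap surrogate proportional to motion for rigid
    translation.  The first frame has no predecessor, so its value
    duplicates the second's, keeping the trace length equal to the number
    of frames.
    """
    frames = np.asarray(frames, dtype=float)
    masks = np.asarray(masks).astype(bool)
    if frames.shape != masks.shape:
        raise ValueError("frames and masks must be aligned stacks of equal shape")
    n = frames.shape[0]
    if n < 2:
        raise ValueError("need at least two frames")
    vals = np.zeros(n)
    for i in range(1, n):
        mask = masks[i]
        if not mask.any():
            warnings.warn(f"empty mask at frame {i}; intensity set to 0")
            continue
        if method == "flow":
            from skimage.registration import optical_flow_ilk
            v, u = optical_flow_ilk(frames[i - 1], frames[i])
            mag = np.hypot(u, v)
        elif method == "framediff":
            mag = np.abs(frames[i] - frames[i - 1])
        else:
            raise ValueError(f"unknown method {method!r}")
        vals[i] = float(mag[mask].sum())
    vals[0] = vals[1]
    return MovementTrace(intensity=vals, frame_rate_hz=frame_rate_hz)


def smooth_trace(trace: MovementTrace, span_frames: int = 90) -> MovementTrace:
    """Centered moving average; edges use shrinking windows (min_periods=1)."""
    if span_frames < 1:
        raise ValueError("span must be >= 1")
    if span_frames > len(trace.intensity):
        raise ValueError("span exceeds trace length")
    sm = (pd.Series(trace.intensity)
          .rolling(window=span_frames, center=True, min_periods=1)
          .mean().to_numpy())
    return MovementTrace(intensity=sm, frame_rate_hz=trace.frame_rate_hz, smoothed=True)


def resample_to_rate_base(trace: MovementTrace, rate: RateVector) -> np.ndarray:
    """Linear interpolation of the movement trace at the rate-bin centers."""
    t = trace.times_s
    centers = rate.bin_centers_s
    if centers[0] < t[0] - 1.0 / trace.frame_rate_hz or centers[-1] > t[-1] + 1.0 / trace.frame_rate_hz:
        raise ValueError("movement trace does not cover the rate vector's time span")
    return np.interp(centers, t, trace.intensity)


def xcov_coeff(a: np.ndarray, b: np.ndarray, max_lag_s: float,
               bin_width_s: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient-scaled cross-covariance of two equal-length vectors.

    curve(l) = sum_t (a_t - mean a)(b_{t+l} - mean b) / sqrt(c_aa(0) c_bb(0)),
    evaluated on the symmetric lag grid |lag| <= max_lag_s (in seconds,
    multiples of the bin width).  The lag-0 auto-covariance of each vector
    normalizes to 1, so every value lies in [-1, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D vectors of length >= 2")
    da = a - a.mean()
    db = b - b.mean()
    norm = np.sqrt((da @ da) * (db @ db))
    if norm == 0:
        raise ValueError("zero-variance vector: coeff normalization undefined")
    full = scipy.signal.correlate(db, da, mode="full", method="auto")
    lags = scipy.signal.correlation_lags(len(b), len(a), mode="full")
    max_lag_bins = int(np.floor(max_lag_s / bin_width_s + 1e-9))
    keep = np.abs(lags) <= max_lag_bins
    return lags[keep] * bin_width_s, full[keep] / norm


@dataclass(frozen=True)
class XcovResult:
    """Per-trial mean matched and shuffled cross-covariance curves."""

    lags_s: np.ndarray
    matched_curve: np.ndarray
    shuffled_curve: np.ndarray
    trial_id: str = ""


def matched_shuffled(iso_movement: np.ndarray, iso_rate: np.ndarray,
                     reiso_movement: np.ndarray, reiso_rate: np.ndarray,
                     max_lag_s: float = 60.0, bin_width_s: float = 3.0,
                     trial_id: str = "") -> XcovResult | None:
    """Matched (same-session) vs shuffled (crossed-session) mean curves.

    Matched averages xcov(iso movement, iso rate) and xcov(re-iso
    movement, re-iso rate); shuffled averages the two crossed pairings.
    Trials in which a session produced zero USVs (zero rate variance)
    cannot be normalized and are excluded: returns None.
    """
    vectors = [iso_movement, iso_rate, reiso_movement, reiso_rate]
    if any(np.ptp(np.asarray(v, dtype=float)) == 0 for v in vectors):
        return None
    lags, m1 = xcov_coeff(iso_movement, iso_rate, max_lag_s, bin_width_s)
    _, m2 = xcov_coeff(reiso_movement, reiso_rate, max_lag_s, bin_width_s)
    _, s1 = xcov_coeff(iso_movement, reiso_rate, max_lag_s, bin_width_s)
    _, s2 = xcov_coeff(reiso_movement, iso_rate, max_lag_s, bin_width_s)
    return XcovResult(lags_s=lags, matched_curve=(m1 + m2) / 2.0,
                      shuffled_curve=(s1 + s2) / 2.0, trial_id=trial_id)


@dataclass(frozen=True)
class PooledCc:
    pooled_lag_s: float
    pooled_cc: float
    per_trial_ccs: np.ndarray


def pooled_cc(curves: list[np.ndarray], lags_s: np.ndarray,
              window_s: float = 5.0) -> PooledCc:
    """Group-level covariance coefficient.

    The mean pooled curve's maximum within |lag| <= window_s defines the
    pooled lag and pooled CC; each trial's CC is its own curve's value at
    that lag.  Ties in the maximum resolve to the lag closest to 0.
    """
    if not curves:
        raise ValueError("need at least one trial curve")
    stack = np.vstack(curves)
    mean_curve = stack.mean(axis=0)
    in_window = np.abs(lags_s) <= window_s + 1e-9
    if not in_window.any():
        raise ValueError("no lags inside the pooling window")
    win_lags = lags_s[in_window]
    win_vals = mean_curve[in_window]
    best = win_vals.max()
    tied = np.flatnonzero(np.isclose(win_vals, best, rtol=0, atol=1e-12))
    pick = tied[np.argmin(np.abs(win_lags[tied]))]
    lag = float(win_lags[pick])
    col = int(np.flatnonzero(np.isclose(lags_s, lag))[0])
    return PooledCc(pooled_lag_s=lag, pooled_cc=float(best),
                    per_trial_ccs=stack[:, col].copy())
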