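"""USV syllable detection from ultrasonic audio.

Detection is a threshold cascade on short-time spectrogram frames: a frame
belongs to a putative syllable iff its band-limited power-weighted mean
frequency exceeds 45 kHz, its spectral purity (fraction of band power in
the single strongest bin) exceeds 0.3, and its dominant frequency moves by
less than 1.00 kHz from the previous frame.  Runs of passing frames become
candidates; candidates closer than the minimum inter-syllable interval
(30 ms) are merged, and candidates shorter than the minimum duration
(5 ms) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

USV_BAND_KHZ = (25.0, 110.0)


@dataclass(frozen=True)
class StftParams:
    """Short-time Fourier transform front-end parameters.

    Defaults (nperseg=1024, noverlap=512 at 250 kHz) give a 4.096-ms
    analysis window with a 2.048-ms hop and 244-Hz frequency bins —
    enough temporal resolution to resolve 5-ms syllables.
    """

    nperseg: int = 1024
    noverlap: int = 512
    window: str = "hann"
    sample_rate_hz: float = 250_000.0

    def __post_init__(self) -> None:
        if not (0 <= self.noverlap < self.nperseg):
            raise ValueError("require 0 <= noverlap < nperseg")

    @property
    def hop_s(self) -> float:
        return (self.nperseg - self.noverlap) / self.sample_rate_hz


@dataclass(frozen=True)
class DetectionThresholds:
    """The five-criterion detection cascade."""

    min_mean_freq_khz: float = 45.0
    min_spectral_purity: float = 0.3
    max_spectral_discontinuity_khz: float = 1.00
    min_duration_ms: float = 5.0
    min_isi_ms: float = 30.0

    def __post_init__(self) -> None:
        vals = (self.min_mean_freq_khz, self.min_spectral_purity,
                self.max_spectral_discontinuity_khz, self.min_duration_ms, self.min_isi_ms)
        if any(v <= 0 for v in vals):
            raise ValueError("all detection thresholds must be positive")
        if self.min_spectral_purity > 1.0:
            raise ValueError("spectral purity threshold must be in (0, 1]")


@dataclass(frozen=True)
class Spectrogram:
    """One-sided power spectrogram with a kHz frequency axis.

    ``frame_times_s`` are window centers; the frame step is
    ``(nperseg - noverlap) / sample_rate``.
    """

    power: np.ndarray  # (freq, time)
    frame_times_s: np.ndarray
    freq_bins_khz: np.ndarray
    params: StftParams

    @property
    def hop_s(self) -> float:
        return self.params.hop_s

    @property
    def bin_width_khz(self) -> float:
        return float(self.freq_bins_khz[1] - self.freq_bins_khz[0])


@dataclass(frozen=True)
class UsvSegment:
    """One detected syllable: half-open [onset, offset) in seconds from file
    start, with the per-frame dominant-frequency trace across its frames."""

    onset_s: float
    offset_s: float
    dominant_freq_trace_khz: np.ndarray
    trial_id: str = ""
    session: str = "isolation"

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1000.0


def compute_spectrogram(audio: np.ndarray, params: StftParams,
                        single_precision: bool = True) -> Spectrogram:
    """STFT power spectrogram.  Single precision (default) is ample for the
    frame metrics (sub-bin peak refinement included) and much faster on
    long ultrasonic recordings."""
    audio = np.asarray(audio)
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio contains non-finite samples")
    if len(audio) < params.nperseg:
        raise ValueError(
            f"audio has {len(audio)} samples; need at least nperseg={params.nperseg}"
        )
    audio = audio.astype(np.float32 if single_precision else np.float64, copy=False)
    freqs, times, power = scipy.signal.spectrogram(
        audio, fs=params.sample_rate_hz, window=params.window,
        nperseg=params.nperseg, noverlap=params.noverlap,
        detrend=False, mode="psd",
    )
    return Spectrogram(power=power, frame_times_s=times,
                       freq_bins_khz=freqs / 1000.0, params=params)


def frame_metrics(spec: Spectrogram, band_khz: tuple[float, float] = USV_BAND_KHZ,
                  refine_peak: bool = True) -> dict[str, np.ndarray]:
    """Per-frame spectral metrics within the analysis band.

    Returns ``mean_freq_khz`` (power-weighted mean frequency),
    ``spectral_purity`` (max-bin power / total band power),
    ``dominant_freq_khz`` (argmax-bin frequency, optionally refined by
    parabolic interpolation of log power for sub-bin accuracy),
    ``spectral_discontinuity_khz`` (|change in dominant frequency| from the
    previous frame; 0 for the first frame) and ``valid`` (False where a
    frame has no power in the band — such frames fail all criteria).
    """
    lo, hi = band_khz
    sel = (spec.freq_bins_khz >= lo) & (spec.freq_bins_khz <= hi)
    if not sel.any():
        raise ValueError(f"band {band_khz} kHz outside the frequency axis")
    band_f = spec.freq_bins_khz[sel]
    band_p = spec.power[sel, :]
    total = band_p.sum(axis=0)
    valid = total > 0
    safe_total = np.where(valid, total, 1.0)
    mean_freq = (band_f[:, None] * band_p).sum(axis=0) / safe_total
    peak_idx = band_p.argmax(axis=0)
    peak_power = band_p[peak_idx, np.arange(band_p.shape[1])]
    purity = peak_power / safe_total
    dominant = band_f[peak_idx].astype(float)
    if refine_peak:
        dominant = _parabolic_refine(band_p, band_f, peak_idx, dominant)
    mean_freq = np.where(valid, mean_freq, np.nan)
    purity = np.where(valid, purity, 0.0)
    dominant = np.where(valid, dominant, np.nan)
    disc = np.zeros_like(dominant)
    if len(dominant) > 1:
        d = np.abs(np.diff(dominant))
        disc[1:] = np.where(np.isfinite(d), d, np.inf)
    return {
        "mean_freq_khz": mean_freq,
        "spectral_purity": purity,
        "dominant_freq_khz": dominant,
        "spectral_discontinuity_khz": disc,
        "valid": valid,
    }


def _parabolic_refine(band_p: np.ndarray, band_f: np.ndarray, peak_idx: np.ndarray,
                      dominant: np.ndarray) -> np.ndarray:
    """Sub-bin peak localization: fit a parabola to log power at the argmax
    bin and its neighbors; skip frames whose peak sits on a band edge."""
    n_bins, n_frames = band_p.shape
    interior = (peak_idx > 0) & (peak_idx < n_bins - 1)
    cols = np.arange(n_frames)[interior]
    k = peak_idx[interior]
    trip = np.stack([band_p[k - 1, cols], band_p[k, cols], band_p[k + 1, cols]])
    ok = (trip > 0).all(axis=0)
    if ok.any():
        lp = np.log(trip[:, ok])
        denom = lp[0] - 2 * lp[1] + lp[2]
        delta = np.where(denom < 0, 0.5 * (lp[0] - lp[2]) / denom, 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        bw = band_f[1] - band_f[0]
        out = dominant.copy()
        out[cols[ok]] = band_f[k[ok]] + delta * bw
        return out
    return dominant


def detect_usvs(spec: Spectrogram, thresholds: DetectionThresholds = DetectionThresholds(),
                band_khz: tuple[float, float] = USV_BAND_KHZ,
                trial_id: str = "", session: str = "isolation") -> list[UsvSegment]:
    """Detect syllables by the five-criterion cascade.

    Frames pass iff mean frequency, purity and discontinuity criteria all
    hold; runs of passing frames are merged across gaps shorter than
    ``min_isi_ms`` first, and merged candidates shorter than
    ``min_duration_ms`` are then discarded (merge-then-filter order: two
    nearby sub-threshold fragments can jointly form a valid syllable).
    """
    m = frame_metrics(spec, band_khz)
    passing = (
        m["valid"]
        & (m["mean_freq_khz"] > thresholds.min_mean_freq_khz)
        & (m["spectral_purity"] > thresholds.min_spectral_purity)
        & (m["spectral_discontinuity_khz"] < thresholds.max_spectral_discontinuity_khz)
    )
    runs = _find_runs(passing)
    if not runs:
        return []
    times = spec.frame_times_s
    half_hop = spec.hop_s / 2.0
    # merge candidates separated by < min_isi_ms of non-passing time
    merged = [runs[0]]
    for i0, i1 in runs[1:]:
        gap_s = times[i0] - times[merged[-1][1]]
        if gap_s < thresholds.min_isi_ms / 1000.0:
            merged[-1] = (merged[-1][0], i1)
        else:
            merged.append((i0, i1))
    segments = []
    for i0, i1 in merged:
        onset = times[i0] - half_hop
        offset = times[i1] + half_hop
        if (offset - onset) * 1000.0 < thresholds.min_duration_ms:
            continue
        segments.append(UsvSegment(
            onset_s=float(onset), offset_s=float(offset),
            dominant_freq_trace_khz=m["dominant_freq_khz"][i0:i1 + 1].copy(),
            trial_id=trial_id, session=session,
        ))
    return segments


def _find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) frame indices of each True run."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(a), int(b - 1)) for a, b in zip(idx[::2], idx[1::2])]
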