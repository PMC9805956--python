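"""The eight pre-defined per-syllable acoustic features.

Per syllable: (1) duration (ms); (2) inter-syllable interval (onset-to-
onset, in ms; intervals over 400 ms are excluded as separate bouts);
(3) mean pitch (kHz; the dominant-frequency trace averaged over the
syllable); (4) pitch slope (kHz/ms; change in dominant frequency from
start to end over the duration); (5) mean frequency (power-weighted mean
in the 25-110 kHz band, averaged over frames); (6) its standard deviation
across frames; (7) spectral purity (frame values averaged); and (8) the
frequency-modulation (FM) index.

The FM index normalizes time within the syllable to [0, 1], divides the
dominant-frequency trace by the syllable's mean pitch, takes the natural
log, and reports the standard deviation of those log ratios: 0 for a
constant-pitch call, larger for strongly modulated calls, and invariant
to overall pitch scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import Spectrogram, UsvSegment, frame_metrics, USV_BAND_KHZ

ISI_EXCLUSION_MS = 400.0


@dataclass(frozen=True)
class AcousticFeatures:
    duration_ms: float
    isi_ms: float | None
    mean_pitch_khz: float
    pitch_slope_khz_per_ms: float
    mean_freq_khz: float
    sd_mean_freq_khz: float
    spectral_purity: float
    fm_index: float
    single_frame: bool = False  # degenerate segment; slope/spread set to 0

    def as_dict(self) -> dict[str, float | None]:
        return {
            "duration_ms": self.duration_ms,
            "isi_ms": self.isi_ms,
            "mean_pitch_khz": self.mean_pitch_khz,
            "pitch_slope_khz_per_ms": self.pitch_slope_khz_per_ms,
            "mean_freq_khz": self.mean_freq_khz,
            "sd_mean_freq_khz": self.sd_mean_freq_khz,
            "spectral_purity": self.spectral_purity,
            "fm_index": self.fm_index,
        }


FEATURE_COLUMNS = list(AcousticFeatures(1, None, 1, 0, 1, 0, 1, 0).as_dict())


def fm_index(dominant_freq_trace_khz: np.ndarray, mean_pitch_khz: float) -> float:
    """Standard deviation (sample, n-1) of log(f(tau) / mean pitch)."""
    trace = np.asarray(dominant_freq_trace_khz, dtype=float)
    if np.any(trace <= 0) or mean_pitch_khz <= 0:
        raise ValueError("dominant-frequency trace and mean pitch must be positive")
    if len(trace) < 2:
        return 0.0
    return float(np.std(np.log(trace / mean_pitch_khz), ddof=1))


def compute_features(segment: UsvSegment, spec: Spectrogram,
                     next_onset_s: float | None = None,
                     band_khz: tuple[float, float] = USV_BAND_KHZ,
                     metrics: dict | None = None) -> AcousticFeatures:
    """Compute the eight features for one syllable from the spectrogram.

    ``next_onset_s`` is the onset of the following syllable in the same
    session (None for the last one); onset-to-onset intervals above 400 ms
    yield a null ISI.  ``metrics`` accepts precomputed
    :func:`~pupcall.detection.frame_metrics` output to avoid recomputing
    it for every syllable of a session.
    """
    times = spec.frame_times_s
    # Prefer frames whose full analysis window sits inside the syllable:
    # windows straddling an edge mix syllable and background energy and
    # bias the dominant-frequency trace at the endpoints.
    half_win = spec.params.nperseg / spec.params.sample_rate_hz / 2.0
    i0 = int(np.searchsorted(times, segment.onset_s + half_win, side="left"))
    i1 = int(np.searchsorted(times, segment.offset_s - half_win, side="right"))
    if i1 - i0 < 2:  # short syllable: fall back to all spanned frames
        i0 = int(np.searchsorted(times, segment.onset_s, side="left"))
        i1 = int(np.searchsorted(times, segment.offset_s, side="left"))
    if i1 <= i0:
        raise ValueError("segment spans no spectrogram frames")
    m = metrics if metrics is not None else frame_metrics(spec, band_khz)
    trace = m["dominant_freq_khz"][i0:i1]
    frame_times = times[i0:i1]
    frame_mean_freq = m["mean_freq_khz"][i0:i1]
    frame_purity = m["spectral_purity"][i0:i1]

    duration_ms = segment.duration_ms
    isi_ms: float | None = None
    if next_onset_s is not None:
        gap = (next_onset_s - segment.onset_s) * 1000.0
        if gap <= 0:
            raise ValueError("next onset must follow this syllable's onset")
        isi_ms = gap if gap <= ISI_EXCLUSION_MS else None

    single = len(trace) < 2
    if single:
        mean_pitch = float(np.nanmean(trace))
        slope = 0.0
        sd_mean_freq = 0.0
        fm = 0.0
    else:
        # Extend the per-frame trace to the exact syllable boundaries by
        # linear extrapolation of the end segments, then average dominant
        # frequency over the entire [onset, offset) interval (time-weighted
        # trapezoid).  For a linear chirp this recovers the programmed mean
        # pitch and slope independent of how the frame grid falls.
        t0, t1 = frame_times[0], frame_times[-1]
        f_on = trace[0] + (trace[1] - trace[0]) / (frame_times[1] - t0) * (segment.onset_s - t0)
        f_off = trace[-1] + (trace[-1] - trace[-2]) / (t1 - frame_times[-2]) * (segment.offset_s - t1)
        full_t = np.concatenate(([segment.onset_s], frame_times, [segment.offset_s]))
        full_f = np.concatenate(([f_on], trace, [f_off]))
        mean_pitch = float(np.trapezoid(full_f, full_t) / (segment.offset_s - segment.onset_s))
        slope = float((f_off - f_on) / duration_ms)
        sd_mean_freq = float(np.nanstd(frame_mean_freq, ddof=1))
        # FM index on the duration-normalized trace (uniform resampling of
        # the boundary-extended trajectory over tau in [0, 1])
        tau_t = np.linspace(segment.onset_s, segment.offset_s, 50)
        fm = fm_index(np.interp(tau_t, full_t, full_f), mean_pitch)
    return AcousticFeatures(
        duration_ms=duration_ms,
        isi_ms=isi_ms,
        mean_pitch_khz=mean_pitch,
        pitch_slope_khz_per_ms=slope,
        mean_freq_khz=float(np.nanmean(frame_mean_freq)),
        sd_mean_freq_khz=sd_mean_freq,
        spectral_purity=float(np.nanmean(frame_purity)),
        fm_index=fm,
        single_frame=single,
    )


def features_table(segments: list[UsvSegment], spec: Spectrogram,
                   band_khz: tuple[float, float] = USV_BAND_KHZ,
                   **labels) -> pd.DataFrame:
    """Tidy per-syllable feature table for one session.

    ISIs chain onset-to-onset within the session; extra keyword labels
    (pup, age, session, behavior, ...) become constant columns.
    """
    rows = []
    metrics = frame_metrics(spec, band_khz) if segments else None
    for k, seg in enumerate(segments):
        nxt = segments[k + 1].onset_s if k + 1 < len(segments) else None
        feats = compute_features(seg, spec, next_onset_s=nxt, band_khz=band_khz,
                                 metrics=metrics)
        row = {"onset_s": seg.onset_s, "offset_s": seg.offset_s, **feats.as_dict()}
        rows.append(row)
    df = pd.DataFrame(rows, columns=["onset_s", "offset_s"] + FEATURE_COLUMNS)
    df["isi_ms"] = df["isi_ms"].astype(float)  # None -> NaN, keep numeric dtype
    for name, value in labels.items():
        df[name] = value
    return df


def aggregate_per_mouse(features: pd.DataFrame, min_usvs: int = 50,
                        group_col: str = "pup",
                        duration_bin_ms: float = 2.0,
                        pitch_bin_khz: float = 2.0) -> dict:
    """Per-mouse feature medians and binned distributions with inclusion rule.

    Mice contribute only if they produced strictly more than ``min_usvs``
    syllables (strict inequality).  Returns medians per included mouse,
    fixed-width histograms of duration and mean pitch, group sizes, and the
    identities of excluded mice (never silently dropped).
    """
    if group_col not in features.columns:
        raise ValueError(f"features table lacks a '{group_col}' column")
    counts = features.groupby(group_col).size()
    included = counts[counts > min_usvs].index
    excluded = counts[counts <= min_usvs].index.tolist()
    kept = features[features[group_col].isin(included)]
    medians = kept.groupby(group_col)[FEATURE_COLUMNS].median(numeric_only=True)

    def _hist(col: str, width: float) -> pd.DataFrame:
        vals = kept[[group_col, col]].dropna()
        if vals.empty:
            return pd.DataFrame()
        edges = np.arange(0.0, vals[col].max() + width, width)
        out = {}
        for g, sub in vals.groupby(group_col):
            h, _ = np.histogram(sub[col], bins=edges)
            out[g] = h / max(h.sum(), 1)
        return pd.DataFrame(out, index=edges[:-1])

    return {
        "medians": medians,
        "duration_hist": _hist("duration_ms", duration_bin_ms),
        "pitch_hist": _hist("mean_pitch_khz", pitch_bin_khz),
        "n_included": len(included),
        "excluded": excluded,
        "counts": counts,
    }
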