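"""Synthetic trial generator with known ground truth.

Emulates the statistical structure of a pup-isolation recording session:

* chirp-like ultrasonic syllables (linear pitch trajectory, optional
  instantaneous pitch jump at the syllable midpoint) summed over white
  background noise;
* a behavior ethogram tiling the session, with configurable behavior
  proportions;
* a nonnegative, smoothed movement-intensity trace whose mean level
  depends on the ongoing behavior (active behaviors move more than
  lying still);
* USV onsets drawn from an inhomogeneous Poisson process whose rate is
  ``baseline_rate_hz + coupling_gain * movement(t - coupling_lag_s)``,
  realized exactly by thinning a homogeneous Poisson stream.

Every output is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import BEHAVIORS, Ethogram

# Mean movement-intensity level per behavior (arbitrary units). Lying still
# is near-zero by definition ("no visible movement"); locomotion moves most.
BEHAVIOR_MOVEMENT_LEVELS = {
    "locomotion": 1.0,
    "wriggling": 0.8,
    "grooming": 0.6,
    "lying_still": 0.05,
}


@dataclass(frozen=True)
class SyllableSpec:
    """Ground-truth description of one synthetic syllable.

    The pitch trajectory is a linear chirp from ``f_start_khz`` to
    ``f_end_khz``; if ``jump_khz`` is set, the second half of the syllable
    is offset by that amount (an instantaneous pitch step, as seen in
    frequency-jump calls).
    """

    onset_s: float
    duration_ms: float
    f_start_khz: float
    f_end_khz: float
    amplitude: float = 1.0
    jump_khz: float | None = None

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")
        for f in (self.f_start_khz, self.f_end_khz):
            if not (25.0 <= f <= 120.0):
                raise ValueError(f"frequency {f} kHz outside the ultrasonic band [25, 120] kHz")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_ms / 1000.0


def synth_syllable(spec: SyllableSpec, sample_rate_hz: float, taper_ms: float = 1.0) -> np.ndarray:
    """Render one syllable as a waveform.

    The instantaneous frequency sweeps linearly from ``f_start`` to
    ``f_end`` (plus the optional midpoint jump); the amplitude envelope has
    raised-cosine ramps of ``taper_ms`` at each edge to avoid spectral
    splatter at the onsets.
    """
    f_hi = max(spec.f_start_khz, spec.f_end_khz) * 1000.0
    if spec.jump_khz is not None:
        f_hi += abs(spec.jump_khz) * 1000.0
    if f_hi >= sample_rate_hz / 2:
        raise ValueError(
            f"syllable reaches {f_hi/1000:.1f} kHz, at or above the Nyquist frequency "
            f"{sample_rate_hz/2000:.1f} kHz"
        )
    n = max(2, round(spec.duration_ms / 1000.0 * sample_rate_hz))
    tau = np.arange(n) / (n - 1)  # normalized time in [0, 1]
    f_khz = spec.f_start_khz + (spec.f_end_khz - spec.f_start_khz) * tau
    if spec.jump_khz is not None:
        f_khz = f_khz + np.where(tau >= 0.5, spec.jump_khz, 0.0)
    phase = 2.0 * np.pi * np.cumsum(f_khz * 1000.0) / sample_rate_hz
    wave = spec.amplitude * np.sin(phase)
    ramp = min(round(taper_ms / 1000.0 * sample_rate_hz), n // 2)
    if ramp > 0:
        win = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        wave[:ramp] *= win
        wave[-ramp:] *= win[::-1]
    return wave


@dataclass(frozen=True)
class AgeProfile:
    """Distribution of syllable acoustics for one age group.

    Pitch is drawn from a Gaussian mixture (bimodal at younger ages,
    unimodal later); duration from a clipped Gaussian; slope uniform in a
    symmetric range.  A fraction of syllables carry a midpoint pitch jump.
    """

    name: str
    duration_mean_ms: float
    duration_sd_ms: float
    duration_range_ms: tuple[float, float]
    pitch_modes: tuple[tuple[float, float, float], ...]  # (weight, mean_khz, sd_khz)
    slope_max_khz_per_ms: float
    jump_prob: float
    jump_range_khz: tuple[float, float] = (8.0, 15.0)

    def sample_syllable(self, rng: np.random.Generator, onset_s: float) -> SyllableSpec:
        dur = float(np.clip(rng.normal(self.duration_mean_ms, self.duration_sd_ms),
                            *self.duration_range_ms))
        w = np.array([m[0] for m in self.pitch_modes], dtype=float)
        mode = self.pitch_modes[rng.choice(len(self.pitch_modes), p=w / w.sum())]
        pitch = float(np.clip(rng.normal(mode[1], mode[2]), 40.0, 100.0))
        slope = float(rng.uniform(-self.slope_max_khz_per_ms, self.slope_max_khz_per_ms))
        f0 = float(np.clip(pitch - slope * dur / 2.0, 35.0, 108.0))
        f1 = float(np.clip(pitch + slope * dur / 2.0, 35.0, 108.0))
        jump = None
        if rng.random() < self.jump_prob:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            jump = float(sign * rng.uniform(*self.jump_range_khz))
            hi, lo = max(f0, f1) + max(jump, 0), min(f0, f1) + min(jump, 0)
            if hi > 108.0 or lo < 35.0:
                jump = None
        return SyllableSpec(onset_s=onset_s, duration_ms=dur, f_start_khz=f0,
                            f_end_khz=f1, jump_khz=jump)


# Profiles emulate the developmental trends of pup isolation calls: long
# syllables and a bimodal pitch distribution early, shorter syllables with a
# tight unimodal pitch later.
DEFAULT_AGE_PROFILES: dict[str, AgeProfile] = {
    "P5": AgeProfile("P5", 21.0, 6.0, (8.0, 60.0),
                     ((0.5, 55.0, 4.0), (0.5, 85.0, 4.0)), 0.35, 0.30),
    "P10": AgeProfile("P10", 22.0, 5.0, (8.0, 60.0),
                      ((0.5, 60.0, 4.0), (0.5, 88.0, 4.0)), 0.35, 0.30),
    "P15": AgeProfile("P15", 11.0, 3.0, (6.0, 30.0),
                      ((1.0, 75.0, 6.0),), 0.35, 0.05),
}


@dataclass(frozen=True)
class TrialSpec:
    """Parameters of one synthetic 5-min session.

    ``coupling_gain`` is in USVs per second per unit movement intensity;
    ``coupling_lag_s`` delays the vocal response behind movement.  Defaults
    give session USV totals of order 10^2, in the range observed for
    vocal pups.
    """

    session_length_s: float = 300.0
    sample_rate_hz: float = 250_000.0
    noise_floor: float = 0.05
    frame_rate_hz: float = 30.0
    coupling_gain: float = 0.8
    coupling_lag_s: float = 0.0
    baseline_rate_hz: float = 0.1
    behavior_mix: dict[str, float] = field(
        default_factory=lambda: {"locomotion": 0.30, "wriggling": 0.25,
                                 "lying_still": 0.35, "grooming": 0.10})
    seed: int = 0
    age_profile: AgeProfile = DEFAULT_AGE_PROFILES["P10"]
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        mix = self.behavior_mix
        if set(mix) - set(BEHAVIORS) or not math.isclose(sum(mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError(f"behavior_mix must cover {BEHAVIORS} and sum to 1; got {mix}")
        if min(self.coupling_gain, self.baseline_rate_hz, self.noise_floor) < 0:
            raise ValueError("rates and noise_floor must be >= 0")
        if self.session_length_s <= 0 or self.sample_rate_hz <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("session length and rates must be positive")


@dataclass(frozen=True)
class GroundTruth:
    segments: tuple[SyllableSpec, ...]
    ethogram: Ethogram
    movement: np.ndarray  # per-frame intensity, length = frames in session

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.onset_s, s.offset_s, s.f_start_khz, s.f_end_khz) for s in self.segments],
            columns=["onset_s", "offset_s", "f_start_khz", "f_end_khz"],
        )


def _synth_ethogram(spec: TrialSpec, rng: np.random.Generator) -> Ethogram:
    """Tile the session with behavior bouts; behavior drawn iid from the mix
    so long-run time proportions match ``behavior_mix`` in expectation."""
    behaviors = list(spec.behavior_mix)
    probs = np.array([spec.behavior_mix[b] for b in behaviors])
    intervals: list[tuple[float, float, str]] = []
    t = 0.0
    prev = None
    while t < spec.session_length_s - 1e-12:
        dur = float(np.clip(rng.gamma(shape=3.0, scale=5.0), 2.0, 60.0))
        end = min(t + dur, spec.session_length_s)
        beh = behaviors[int(rng.choice(len(behaviors), p=probs))]
        if beh == prev and intervals:
            intervals[-1] = (intervals[-1][0], end, beh)
        else:
            intervals.append((t, end, beh))
        prev = beh
        t = end
    return Ethogram(tuple(intervals), spec.session_length_s)


def _synth_movement(spec: TrialSpec, ethogram: Ethogram, rng: np.random.Generator,
                    noise_sd: float = 0.3, smooth_frames: int = 15) -> np.ndarray:
    """Rectified, moving-average-smoothed Gaussian process with per-behavior
    mean levels.  Frame i represents time (i + 0.5) / frame_rate."""
    n = round(spec.session_length_s * spec.frame_rate_hz)
    times = (np.arange(n) + 0.5) / spec.frame_rate_hz
    level = np.array([BEHAVIOR_MOVEMENT_LEVELS[ethogram.behavior_at(min(t, spec.session_length_s - 1e-9))]
                      for t in times])
    raw = np.maximum(level + noise_sd * level ** 0.5 * rng.standard_normal(n), 0.0)
    kernel = np.ones(smooth_frames) / smooth_frames
    pad = smooth_frames // 2
    padded = np.pad(raw, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[:n]


def _poisson_onsets(spec: TrialSpec, movement: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson onsets by thinning a homogeneous stream with
    rate(t) = baseline + gain * movement(t - lag) (edge-held before t=lag)."""
    times = (np.arange(len(movement)) + 0.5) / spec.frame_rate_hz

    def rate_at(t: np.ndarray) -> np.ndarray:
        return spec.baseline_rate_hz + spec.coupling_gain * np.interp(
            t - spec.coupling_lag_s, times, movement)

    lam_max = spec.baseline_rate_hz + spec.coupling_gain * float(movement.max(initial=0.0))
    if lam_max <= 0:
        return np.array([])
    n_cand = rng.poisson(lam_max * spec.session_length_s)
    cand = np.sort(rng.uniform(0.0, spec.session_length_s, size=n_cand))
    keep = rng.uniform(0.0, lam_max, size=n_cand) < rate_at(cand)
    return cand[keep]


def _fixed_count_onsets(spec: TrialSpec, n_syllables: int, rng: np.random.Generator,
                        min_gap_s: float = 0.15) -> np.ndarray:
    """Uniform random onsets with a minimum gap, for controlled detector tests."""
    max_dur_s = spec.age_profile.duration_range_ms[1] / 1000.0
    slack = spec.session_length_s - max_dur_s - n_syllables * min_gap_s
    if slack <= 0:
        raise ValueError("session too short for requested syllable count and spacing")
    u = np.sort(rng.uniform(0.0, slack, size=n_syllables))
    return u + min_gap_s * np.arange(n_syllables)


def synth_trial(spec: TrialSpec, n_syllables: int | None = None,
                render_audio: bool = True) -> tuple[np.ndarray | None, GroundTruth]:
    """Generate one session: audio plus ground-truth segments, ethogram and
    movement trace.

    With ``n_syllables`` set, onsets are drawn uniformly with a minimum gap
    instead of from the coupled Poisson process (a controlled regime for
    detector benchmarking).  ``render_audio=False`` skips waveform synthesis
    (the rate/movement analyses only need event times).
    """
    rng = np.random.default_rng(spec.seed)
    ethogram = _synth_ethogram(spec, rng)
    movement = _synth_movement(spec, ethogram, rng)
    if n_syllables is not None:
        onsets = _fixed_count_onsets(spec, n_syllables, rng)
    else:
        onsets = _poisson_onsets(spec, movement, rng)
    segments = []
    for t in onsets:
        syl = spec.age_profile.sample_syllable(rng, float(t))
        if spec.amplitude != 1.0:
            syl = replace(syl, amplitude=spec.amplitude)
        if syl.offset_s <= spec.session_length_s:
            segments.append(syl)
    truth = GroundTruth(tuple(segments), ethogram, movement)
    if not render_audio:
        return None, truth
    n = round(spec.session_length_s * spec.sample_rate_hz)
    audio = spec.noise_floor * rng.standard_normal(n) if spec.noise_floor > 0 else np.zeros(n)
    for syl in segments:
        wave = synth_syllable(syl, spec.sample_rate_hz)
        i0 = round(syl.onset_s * spec.sample_rate_hz)
        audio[i0:i0 + len(wave)] += wave[: max(0, n - i0)]
    return audio, truth


def synth_cohort(age_profiles: dict[str, AgeProfile], n_pups: int, seed: int,
                 spec: TrialSpec | None = None, n_syllables: int | None = None,
                 render_audio: bool = True) -> list[tuple[str, int, np.ndarray | None, GroundTruth]]:
    """Generate ``n_pups`` trials per age profile.

    Returns tuples ``(age, pup_id, audio, ground_truth)``.  At least two
    pups per group are required so repertoire comparisons can form
    pup-level within-group splits.
    """
    if len(age_profiles) < 2:
        raise ValueError("need at least 2 distinct age profiles")
    if n_pups < 2:
        raise ValueError("need at least 2 pups per group (within-group MMD splits)")
    base = spec or TrialSpec()
    out = []
    root = np.random.default_rng(seed)
    for age, profile in age_profiles.items():
        for pup in range(n_pups):
            sub_seed = int(root.integers(0, 2**31 - 1))
            tspec = replace(base, seed=sub_seed, age_profile=profile)
            audio, truth = synth_trial(tspec, n_syllables=n_syllables,
                                       render_audio=render_audio)
            out.append((age, pup, audio, truth))
    return out


def sample_feature_table(profile: AgeProfile, n: int, rng: np.random.Generator,
                         mean_isi_ms: float = 180.0) -> pd.DataFrame:
    """Idealized per-syllable feature table drawn directly from a profile.

    Computes the eight features analytically from each sampled chirp
    (no audio rendering): useful for repertoire-level simulations where
    only the feature distribution matters.
    """
    rows = []
    for _ in range(n):
        syl = profile.sample_syllable(rng, 0.0)
        tau = np.linspace(0.0, 1.0, 50)
        f = syl.f_start_khz + (syl.f_end_khz - syl.f_start_khz) * tau
        if syl.jump_khz is not None:
            f = f + np.where(tau >= 0.5, syl.jump_khz, 0.0)
        mean_pitch = float(f.mean())
        fm = float(np.std(np.log(f / mean_pitch), ddof=1))
        isi = float(rng.exponential(mean_isi_ms))
        rows.append({
            "duration_ms": syl.duration_ms,
            "isi_ms": isi if isi <= 400.0 else np.nan,
            "mean_pitch_khz": mean_pitch,
            "pitch_slope_khz_per_ms": (f[-1] - f[0]) / syl.duration_ms,
            "mean_freq_khz": mean_pitch,
            "sd_mean_freq_khz": float(np.std(f, ddof=1)),
            "spectral_purity": float(np.clip(rng.normal(0.8, 0.05), 0.3, 1.0)),
            "fm_index": fm,
        })
    return pd.DataFrame(rows)
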