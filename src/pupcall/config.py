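"""Validated pipeline configuration (YAML-backed).

Unknown keys are rejected so a typo in a config file fails loudly rather
than silently running with a default.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .behavior import BEHAVIORS


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StftConfig(_Strict):
    nperseg: int = 1024
    noverlap: int = 512
    window: str = "hann"
    sample_rate_hz: float = 250_000.0

    @field_validator("noverlap")
    @classmethod
    def _overlap(cls, v, info):
        if v < 0:
            raise ValueError("noverlap must be >= 0")
        return v


class ThresholdConfig(_Strict):
    min_mean_freq_khz: float = 45.0
    min_spectral_purity: float = Field(default=0.3, gt=0.0, le=1.0)
    max_spectral_discontinuity_khz: float = Field(default=1.00, gt=0.0)
    min_duration_ms: float = Field(default=5.0, gt=0.0)
    min_isi_ms: float = Field(default=30.0, gt=0.0)


class SimulateConfig(_Strict):
    session_length_s: float = 300.0
    noise_floor: float = 0.05
    frame_rate_hz: float = 30.0
    coupling_gain: float = 0.8
    coupling_lag_s: float = 0.0
    baseline_rate_hz: float = 0.1
    behavior_mix: dict[str, float] = {
        "locomotion": 0.30, "wriggling": 0.25, "lying_still": 0.35, "grooming": 0.10}
    n_pups: int = 2
    ages: list[str] = ["P5", "P10", "P15"]

    @field_validator("behavior_mix")
    @classmethod
    def _mix(cls, v):
        if set(v) - set(BEHAVIORS) or abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError(f"behavior_mix must cover {BEHAVIORS} and sum to 1")
        return v


class XcovConfig(_Strict):
    bin_width_s: float = 3.0
    span_frames: int = 90
    max_lag_s: float = 60.0
    cc_window_s: float = 5.0


class MmdConfig(_Strict):
    kernel: str = "rbf"
    bandwidth: float | None = None  # None = median heuristic
    unbiased: bool = True
    n_baseline_splits: int = 10


class PipelineConfig(_Strict):
    stft: StftConfig = StftConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    simulate: SimulateConfig = SimulateConfig()
    xcov: XcovConfig = XcovConfig()
    mmd: MmdConfig = MmdConfig()
    seed: int = 0
    min_usvs_per_mouse: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
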