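"""File I/O for the pipeline's standard artifacts.

Audio is float32 PCM WAV (via scipy); tabular artifacts are plain CSV so
every stage's output reloads into the next stage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io.wavfile

from .behavior import Ethogram
from .detection import UsvSegment


def write_wav(path: str | Path, audio: np.ndarray, sample_rate_hz: float) -> None:
    scipy.io.wavfile.write(str(path), int(sample_rate_hz), audio.astype(np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    rate, data = scipy.io.wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = data.astype(np.float64)
    return data, float(rate)


def write_segments(path: str | Path, segments: list[UsvSegment]) -> None:
    """Segments CSV plus an NPZ sidecar with per-segment dominant-frequency
    traces (variable-length, keyed seg_<row index>)."""
    df = pd.DataFrame(
        [(s.trial_id, s.session, s.onset_s, s.offset_s) for s in segments],
        columns=["trial_id", "session", "onset_s", "offset_s"],
    )
    df.to_csv(path, index=False)
    traces = {f"seg_{i}": s.dominant_freq_trace_khz for i, s in enumerate(segments)}
    np.savez(Path(path).with_suffix(".traces.npz"), **traces)


def read_segments(path: str | Path) -> list[UsvSegment]:
    df = pd.read_csv(path)
    sidecar = Path(path).with_suffix(".traces.npz")
    traces = dict(np.load(sidecar)) if sidecar.exists() else {}
    out = []
    for i, row in df.iterrows():
        out.append(UsvSegment(
            onset_s=float(row["onset_s"]), offset_s=float(row["offset_s"]),
            dominant_freq_trace_khz=traces.get(f"seg_{i}", np.array([])),
            trial_id=str(row["trial_id"]), session=str(row["session"]),
        ))
    return out


def write_ethogram(path: str | Path, ethogram: Ethogram) -> None:
    ethogram.to_frame().to_csv(path, index=False)


def read_ethogram(path: str | Path) -> Ethogram:
    return Ethogram.from_frame(pd.read_csv(path))


def write_movement(path: str | Path, intensity: np.ndarray) -> None:
    pd.DataFrame({"frame_idx": np.arange(len(intensity)),
                  "intensity": intensity}).to_csv(path, index=False)


def read_movement(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["intensity"].to_numpy(dtype=float)
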