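import numpy as np
import pytest

from pupcall.detection import StftParams, compute_spectrogram
from pupcall.synthetic import SyllableSpec, TrialSpec, synth_syllable, synth_trial

SR = 250_000.0
BIN_KHZ = SR / 1024 / 1000.0  # STFT frequency-bin width at the defaults


@pytest.fixture(scope="session")
def stft():
    return StftParams(sample_rate_hz=SR)


def render_syllable(spec: SyllableSpec, pad_s: float = 0.1, noise: float = 0.0,
                    seed: int = 0, stft_params: StftParams | None = None):
    """Place one syllable in a padded clip and return (audio, spectrogram)."""
    total = spec.offset_s + pad_s
    n = int(total * SR)
    rng = np.random.default_rng(seed)
    audio = noise * rng.standard_normal(n) if noise > 0 else np.zeros(n)
    w = synth_syllable(spec, SR)
    i0 = int(spec.onset_s * SR)
    audio[i0:i0 + len(w)] += w
    return audio, compute_spectrogram(audio, stft_params or StftParams(sample_rate_hz=SR))


@pytest.fixture(scope="session")
def clean_trial():
    """One 60-s noise-backed trial with 50 programmed syllables (shared by
    detection and conservation tests; generation dominates test cost)."""
    spec = TrialSpec(session_length_s=60.0, seed=1)
    audio, truth = synth_trial(spec, n_syllables=50)
    sgram = compute_spectrogram(audio, StftParams(sample_rate_hz=SR))
    return spec, audio, truth, sgram
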