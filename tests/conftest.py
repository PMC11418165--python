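import numpy as np
import pytest

from geckovox.audio import AudioClip


@pytest.fixture
def tone():
    """Factory for pure-tone clips."""

    def make(freq_hz: float, duration_s: float = 1.0, fs: float = 44100.0,
             amplitude: float = 1.0) -> AudioClip:
        t = np.arange(int(duration_s * fs)) / fs
        return AudioClip(samples=amplitude * np.sin(2 * np.pi * freq_hz * t),
                         sample_rate_hz=fs)

    return make


@pytest.fixture(scope="session")
def call_dataset():
    """Small labeled synthetic call population shared across tests."""
    from geckovox.synth import synth_call_dataset

    return synth_call_dataset(n_per_type=5, n_individuals=3, seed=1)
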