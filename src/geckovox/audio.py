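"""Audio containers and 16-bit PCM WAV input/output.

The unit of acoustic analysis is the :class:`AudioClip`: a mono waveform with
its sample rate and recording metadata (individual id, call-type label).
Call-type labels follow the field typology for tokay alarm calls:
``type1`` (sinusoidal), ``type2`` (intermediate), ``type3`` (pulse train).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

CALL_TYPES = ("type1", "type2", "type3")

__all__ = ["AudioClip", "CallSegment", "read_wav", "write_wav", "CALL_TYPES"]


@dataclass
class AudioClip:
    """A mono waveform with sample rate and metadata.

    Parameters
    ----------
    samples
        Dimensionless amplitudes, nominally in [-1, 1].
    sample_rate_hz
        Sampling rate in Hz (44100 for the recordings emulated here).
    individual_id
        Identifier of the recorded animal, or "" if unknown.
    call_type
        One of ``type1 | type2 | type3 | unlabeled``.
    source
        Free-text provenance (filename, generator parameters, ...).
    """

    samples: np.ndarray
    sample_rate_hz: float
    individual_id: str = ""
    call_type: str = "unlabeled"
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.call_type not in CALL_TYPES + ("unlabeled",):
            raise ValueError(f"unknown call_type {self.call_type!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz

    def with_samples(self, samples: np.ndarray) -> "AudioClip":
        """Copy of this clip with new samples, metadata preserved."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class CallSegment:
    """Half-open sample-index range [start_index, end_index) of one call
    excised from a longer recorded sequence."""

    start_index: int
    end_index: int
    parent: AudioClip = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.start_index < 0 or self.end_index <= self.start_index:
            raise ValueError("need 0 <= start_index < end_index")
        if self.parent is not None and self.end_index > len(self.parent):
            raise ValueError("segment extends past parent clip")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    def extract(self) -> AudioClip:
        if self.parent is None:
            raise ValueError("segment has no parent clip")
        return self.parent.with_samples(
            self.parent.samples[self.start_index : self.end_index]
        )


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM mono WAV, clipping to [-1, 1]."""
    x = np.clip(clip.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(round(clip.sample_rate_hz)), pcm)


def read_wav(
    path: str | Path,
    individual_id: str = "",
    call_type: str = "unlabeled",
) -> AudioClip:
    """Read a WAV file into an AudioClip, scaling integer PCM to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:  # fold multi-channel to mono
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    return AudioClip(
        samples=data,
        sample_rate_hz=float(rate),
        individual_id=individual_id,
        call_type=call_type,
        source=str(path),
    )
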