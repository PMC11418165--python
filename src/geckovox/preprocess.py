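"""Audio front end: high-pass filtering, call excision, normalization.

Recordings are high-pass filtered (100 Hz at acquisition, 250 Hz before
spectral analysis; Butterworth, applied forward-backward for zero phase)
and individual calls are excised from the recorded sequences. Excision is
automated here by envelope thresholding, standing in for manual cutting.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .audio import AudioClip, CallSegment

__all__ = ["highpass_filter", "segment_calls", "normalize_amplitude", "envelope"]


def highpass_filter(clip: AudioClip, cutoff_hz: float, order: int = 4) -> AudioClip:
    """Zero-phase Butterworth high-pass filter.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is |H(f)|^2 and the phase is zero —
    envelope timing is preserved. Output length equals input length and
    metadata is carried over.
    """
    nyq = clip.sample_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff_hz must lie in (0, {nyq}); got {cutoff_hz}")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = sps.butter(order, cutoff_hz, btype="highpass",
                     fs=clip.sample_rate_hz, output="sos")
    return clip.with_samples(sps.sosfiltfilt(sos, clip.samples))


def envelope(clip: AudioClip, smooth_s: float = 0.010) -> np.ndarray:
    """Hilbert magnitude envelope smoothed with a moving average
    (default 10 ms) — robust to intra-call oscillation for onset detection."""
    env = np.abs(sps.hilbert(clip.samples))
    n = max(1, int(round(smooth_s * clip.sample_rate_hz)))
    if n > 1:
        kernel = np.ones(n) / n
        env = np.convolve(env, kernel, mode="same")
    return env


def segment_calls(
    clip: AudioClip,
    threshold_rel: float = 0.05,
    min_gap_s: float = 0.2,
    min_dur_s: float = 0.03,
) -> list[CallSegment]:
    """Excise calls as supra-threshold runs of the smoothed envelope.

    Runs where the envelope exceeds ``threshold_rel`` times its maximum are
    merged across gaps shorter than ``min_gap_s`` and dropped when shorter
    than ``min_dur_s``. Returns disjoint segments sorted by onset; silence
    yields an empty list.
    """
    if not 0 < threshold_rel < 1:
        raise ValueError("threshold_rel must lie in (0, 1)")
    env = envelope(clip)
    peak = env.max()
    if peak <= 0:
        return []
    above = env > threshold_rel * peak
    if not above.any():
        return []

    # maximal runs of True
    idx = np.flatnonzero(above)
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[run_breaks + 1]))
    run_ends = np.concatenate((idx[run_breaks] + 1, [idx[-1] + 1]))

    # merge runs separated by gaps < min_gap_s
    fs = clip.sample_rate_hz
    min_gap = int(round(min_gap_s * fs))
    merged: list[list[int]] = [[int(run_starts[0]), int(run_ends[0])]]
    for s, e in zip(run_starts[1:], run_ends[1:]):
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    min_dur = int(round(min_dur_s * fs))
    return [
        CallSegment(start_index=s, end_index=e, parent=clip)
        for s, e in merged
        if e - s >= min_dur
    ]


def normalize_amplitude(clip: AudioClip) -> AudioClip:
    """Scale so the maximum absolute sample equals 1 (idempotent)."""
    peak = np.max(np.abs(clip.samples))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero clip")
    return clip.with_samples(clip.samples / peak)
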