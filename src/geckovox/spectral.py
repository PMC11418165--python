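"""Frequency-domain characterization of alarm calls.

Two complementary representations are computed per call:

* a **spectrogram** with 4096 FFT points and a Hamming window whose length
  is the signal length divided by 100, giving exactly 100 time bins per
  call and a frequency resolution of fs/4096 (10.8 Hz at 44.1 kHz);
* a **Welch power spectral density** (4096 FFT points, 256-point Hann
  window, 50% overlap), computed after a 250 Hz 6th-order Butterworth
  high-pass.

Per-type population spectra use a two-stage average — mean per individual
first, then the unweighted mean across individuals — so individuals with
many calls do not dominate. Summaries are the peak frequency (argmax of
the PSD, ties toward lower frequency) and the fraction of power within a
band (500 Hz - 5 kHz by default, relative to total power above the 250 Hz
analysis cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .audio import AudioClip
from .preprocess import highpass_filter

__all__ = [
    "Spectrogram",
    "PowerSpectrum",
    "compute_spectrogram",
    "welch_psd",
    "call_psd",
    "average_spectra",
    "peak_frequency",
    "band_power_fraction",
    "TypeAverage",
]

ANALYSIS_HIGHPASS_HZ = 250.0
ANALYSIS_HIGHPASS_ORDER = 6


@dataclass
class Spectrogram:
    times_s: np.ndarray     # bin-center times, length 100 by default
    freqs_hz: np.ndarray    # ascending, spacing = sample_rate / nfft
    power: np.ndarray       # (time, frequency) magnitude-squared


@dataclass
class PowerSpectrum:
    freqs_hz: np.ndarray
    psd: np.ndarray         # one-sided density, amplitude^2 / Hz
    n_calls_averaged: int = 1

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs_hz.shape != self.psd.shape:
            raise ValueError("frequency axis and psd must align")
        if np.any(self.psd < -1e-12):
            raise ValueError("psd must be non-negative")


def compute_spectrogram(clip: AudioClip, nfft: int = 4096,
                        n_time_bins: int = 100) -> Spectrogram:
    """Spectrogram with exactly ``n_time_bins`` non-overlapping windows.

    The window length is floor(len/n_time_bins) samples, Hamming-tapered
    and zero-padded to ``nfft`` points, so the frequency resolution is
    sample_rate/nfft regardless of call length.
    """
    n = len(clip)
    if n < n_time_bins:
        raise ValueError(f"clip must have at least {n_time_bins} samples")
    wl = n // n_time_bins
    fs = clip.sample_rate_hz
    frames = clip.samples[: wl * n_time_bins].reshape(n_time_bins, wl)
    win = np.hamming(wl)
    spec = np.fft.rfft(frames * win, n=nfft, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    times = (np.arange(n_time_bins) + 0.5) * wl / fs
    return Spectrogram(times_s=times, freqs_hz=freqs, power=power)


def welch_psd(clip: AudioClip, nfft: int = 4096,
              window_len: int = 256) -> PowerSpectrum:
    """One-sided Welch PSD: Hann window, 50% overlap, zero-padded FFT."""
    if len(clip) < window_len:
        raise ValueError(f"clip must have at least {window_len} samples")
    freqs, psd = sps.welch(
        clip.samples,
        fs=clip.sample_rate_hz,
        window="hann",
        nperseg=window_len,
        noverlap=window_len // 2,
        nfft=nfft,
        scaling="density",
        detrend=False,
    )
    return PowerSpectrum(freqs_hz=freqs, psd=psd, n_calls_averaged=1)


def call_psd(clip: AudioClip, highpass_hz: float = ANALYSIS_HIGHPASS_HZ,
             highpass_order: int = ANALYSIS_HIGHPASS_ORDER,
             nfft: int = 4096, window_len: int = 256) -> PowerSpectrum:
    """The per-call analysis spectrum: 250 Hz 6th-order high-pass, then
    Welch PSD."""
    return welch_psd(highpass_filter(clip, highpass_hz, highpass_order),
                     nfft=nfft, window_len=window_len)


@dataclass
class TypeAverage:
    """Grand-mean spectrum for one call type with across-individual spread."""

    mean: PowerSpectrum
    sd: np.ndarray              # +-1 s.d. over individual means, per bin
    n_individuals: int
    n_calls: int


def average_spectra(
    spectra: Sequence[PowerSpectrum],
    individual_ids: Sequence[str],
    call_types: Sequence[str],
) -> dict[str, TypeAverage]:
    """Two-stage per-type averaging of call spectra.

    Stage one averages all of an individual's spectra of a given type;
    stage two takes the unweighted mean of those individual averages, so
    the grand mean weights individuals equally regardless of how many
    calls each produced. The returned s.d. is over individual means.
    """
    if not (len(spectra) == len(individual_ids) == len(call_types)):
        raise ValueError("spectra, individual_ids, call_types must align")
    if len(spectra) == 0:
        raise ValueError("no spectra given")
    freqs = spectra[0].freqs_hz
    for s in spectra[1:]:
        if s.freqs_hz.shape != freqs.shape or not np.allclose(s.freqs_hz, freqs):
            raise ValueError("all spectra must share one frequency axis")

    out: dict[str, TypeAverage] = {}
    for ct in sorted(set(call_types)):
        by_ind: dict[str, list[np.ndarray]] = {}
        n_calls = 0
        for s, ind, t in zip(spectra, individual_ids, call_types):
            if t == ct:
                by_ind.setdefault(ind, []).append(s.psd)
                n_calls += 1
        ind_means = np.stack([np.mean(v, axis=0) for v in by_ind.values()])
        grand = ind_means.mean(axis=0)
        sd = (ind_means.std(axis=0, ddof=1) if ind_means.shape[0] > 1
              else np.zeros_like(grand))
        out[ct] = TypeAverage(
            mean=PowerSpectrum(freqs_hz=freqs, psd=grand,
                               n_calls_averaged=n_calls),
            sd=sd,
            n_individuals=ind_means.shape[0],
            n_calls=n_calls,
        )
    return out


def peak_frequency(spectrum: PowerSpectrum) -> float:
    """Frequency of the global PSD maximum; ties break toward lower
    frequency (argmax returns the first index)."""
    if np.all(spectrum.psd == 0):
        raise ValueError("all-zero spectrum has no peak")
    return float(spectrum.freqs_hz[int(np.argmax(spectrum.psd))])


def band_power_fraction(
    spectrum: PowerSpectrum,
    lo_hz: float = 500.0,
    hi_hz: float = 5000.0,
    total_lo_hz: float = ANALYSIS_HIGHPASS_HZ,
) -> float:
    """Fraction of spectral power in [lo, hi] relative to [total_lo, Nyquist].

    Both integrals are trapezoidal over the PSD. The denominator starts at
    the analysis high-pass cutoff (250 Hz) by default: the analyzed signal
    carries no power below it.
    """
    f = spectrum.freqs_hz
    nyq = f[-1]
    if not (total_lo_hz <= lo_hz < hi_hz <= nyq):
        raise ValueError("need total_lo_hz <= lo_hz < hi_hz <= Nyquist")

    def band_integral(a: float, b: float) -> float:
        grid = np.union1d(f[(f >= a) & (f <= b)], [a, b])
        return float(np.trapezoid(np.interp(grid, f, spectrum.psd), grid))

    total = band_integral(total_lo_hz, nyq)
    if total == 0:
        raise ValueError("zero total power in the reference band")
    return band_integral(lo_hz, hi_hz) / total
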