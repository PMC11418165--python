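"""Cepstral feature vectors and PCA separation of call types.

Each call is summarized by 15 mel-frequency cepstral coefficients (MFCCs)
and their delta coefficients over 20 non-overlapping segments (segment
length = call length / 20). The mel filterbank spans 250-5000 Hz — the
hearing range of the tokay gecko — on the HTK mel scale
mel(f) = 2595 log10(1 + f/700). MFCC 0, which encodes overall signal
energy only, is excluded along with its deltas, leaving a
20 x (14 + 14) = 560-dimensional feature vector per call. PCA (mean
centering, no variance scaling) projects the population onto its first
three components; cluster separation of the labeled types is quantified
by per-type mean silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .audio import AudioClip

__all__ = [
    "MelFilterbank",
    "CallFeatures",
    "PCAResult",
    "hz_to_mel",
    "mel_to_hz",
    "build_mel_filterbank",
    "compute_mfcc",
    "delta_coefficients",
    "assemble_feature_vector",
    "call_features",
    "run_pca",
    "cluster_separation",
]

LOG_FLOOR = 1e-12  # clamp on mel energies before the log (silent segments)

# Calls shorter than this are excluded from the PCA: with 20 segments a
# 0.15 s call already gives < 8 ms analysis windows, and the window's
# spectral smearing then dominates the cepstra. The study design likewise
# left its shortest calls out of the PCA.
MIN_PCA_DURATION_S = 0.15


def hz_to_mel(f_hz):
    """HTK mel scale: mel(f) = 2595 * log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f_hz, dtype=float) / 700.0)


def mel_to_hz(mel):
    return 700.0 * (10.0 ** (np.asarray(mel, dtype=float) / 2595.0) - 1.0)


@dataclass
class MelFilterbank:
    n_filters: int
    fmin_hz: float
    fmax_hz: float
    nfft: int
    sample_rate_hz: float
    weights: np.ndarray        # (n_filters, nfft//2 + 1), non-negative
    centers_hz: np.ndarray     # strictly increasing


def build_mel_filterbank(
    n_filters: int = 20,
    fmin_hz: float = 250.0,
    fmax_hz: float = 5000.0,
    nfft: int = 4096,
    fs: float = 44100.0,
) -> MelFilterbank:
    """Triangular filters with centers equally spaced on the mel scale.

    Adjacent filters cross at half height; every filter's support lies
    within [fmin_hz, fmax_hz].
    """
    if not 0 <= fmin_hz < fmax_hz:
        raise ValueError("need 0 <= fmin_hz < fmax_hz")
    if fmax_hz > fs / 2:
        raise ValueError("fmax_hz must not exceed the Nyquist frequency")
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz),
                                     n_filters + 2))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    weights = np.zeros((n_filters, freqs.size))
    for i in range(n_filters):
        lo, center, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (freqs - lo) / (center - lo)
        down = (hi - freqs) / (hi - center)
        weights[i] = np.clip(np.minimum(up, down), 0.0, None)
    return MelFilterbank(
        n_filters=n_filters,
        fmin_hz=fmin_hz,
        fmax_hz=fmax_hz,
        nfft=nfft,
        sample_rate_hz=fs,
        weights=weights,
        centers_hz=edges_hz[1:-1],
    )


@dataclass
class CallFeatures:
    """Per-call MFCC and delta matrices plus the flattened PCA input."""

    mfcc: np.ndarray           # (n_segments, n_coeffs)
    deltas: np.ndarray         # same shape

    @property
    def feature_vector(self) -> np.ndarray:
        return assemble_feature_vector(self)


def compute_mfcc(
    clip: AudioClip,
    fb: MelFilterbank | None = None,
    n_coeffs: int = 15,
    n_segments: int = 20,
) -> np.ndarray:
    """MFCC matrix (n_segments x n_coeffs) for one call.

    The call is split into ``n_segments`` non-overlapping Hamming-windowed
    segments of floor(len/n_segments) samples. Per segment: magnitude-
    squared spectrum (zero-padded to the filterbank's FFT size), mel
    filterbank energies, log (floored at 1e-12), orthonormal DCT-II; the
    first ``n_coeffs`` coefficients are kept.
    """
    if fb is None:
        fb = build_mel_filterbank(fs=clip.sample_rate_hz)
    if abs(fb.sample_rate_hz - clip.sample_rate_hz) > 1e-9:
        raise ValueError("filterbank sample rate does not match clip")
    n = len(clip)
    if n < n_segments:
        raise ValueError(f"clip must have at least {n_segments} samples")
    seg_len = n // n_segments
    frames = clip.samples[: seg_len * n_segments].reshape(n_segments, seg_len)
    win = np.hamming(seg_len)
    spec = np.abs(np.fft.rfft(frames * win, n=fb.nfft, axis=1)) ** 2
    mel_energy = spec @ fb.weights.T
    log_energy = np.log(np.maximum(mel_energy, LOG_FLOOR))
    cepstra = dct(log_energy, type=2, norm="ortho", axis=1)
    return cepstra[:, :n_coeffs]


def delta_coefficients(mfcc: np.ndarray, window: int = 2) -> np.ndarray:
    """Delta (local slope) coefficients over +-``window`` segments.

    Standard regression form: d_t = sum_k k (c_{t+k} - c_{t-k}) / (2 sum k^2),
    with edge segments replicated for padding.
    """
    mfcc = np.asarray(mfcc, dtype=float)
    if mfcc.ndim != 2 or mfcc.shape[0] < 2:
        raise ValueError("need a (segments >= 2, coeffs) matrix")
    pad = np.pad(mfcc, ((window, window), (0, 0)), mode="edge")
    denom = 2.0 * sum(k * k for k in range(1, window + 1))
    out = np.zeros_like(mfcc)
    for k in range(1, window + 1):
        out += k * (pad[window + k : window + k + mfcc.shape[0]]
                    - pad[window - k : window - k + mfcc.shape[0]])
    return out / denom


def assemble_feature_vector(features: CallFeatures) -> np.ndarray:
    """Drop coefficient 0 from MFCCs and deltas, flatten row-major.

    Ordering: the trimmed MFCC matrix (segments x coefficients 1..C-1)
    flattened row-major, followed by the trimmed delta matrix likewise.
    With 20 segments and 15 coefficients the vector has length
    20*(14+14) = 560.
    """
    if features.mfcc.shape != features.deltas.shape:
        raise ValueError("mfcc and delta matrices must have the same shape")
    return np.concatenate(
        [features.mfcc[:, 1:].ravel(), features.deltas[:, 1:].ravel()]
    )


def call_features(clip: AudioClip, fb: MelFilterbank | None = None,
                  n_coeffs: int = 15, n_segments: int = 20) -> CallFeatures:
    """MFCCs plus deltas for one call (the full cepstral front end)."""
    mfcc = compute_mfcc(clip, fb=fb, n_coeffs=n_coeffs, n_segments=n_segments)
    return CallFeatures(mfcc=mfcc, deltas=delta_coefficients(mfcc))


@dataclass
class PCAResult:
    loadings: np.ndarray                    # (n_features, n_components)
    scores: np.ndarray                      # (n_calls, n_components)
    explained_variance_fraction: np.ndarray
    mean: np.ndarray                        # per-feature centering vector


def run_pca(vectors: np.ndarray, n_components: int | None = None) -> PCAResult:
    """PCA of the feature matrix: mean centering, no variance scaling.

    Components come from the SVD of the centered matrix; the sign of each
    component is fixed so its largest-magnitude loading is positive, which
    makes scores reproducible across runs.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a (calls >= 2, features >= 1) matrix")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T
    # deterministic sign: largest |loading| per component made positive
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
    )


def cluster_separation(scores: np.ndarray, labels) -> dict[str, float]:
    """Mean silhouette per call-type label on the given score columns.

    Euclidean distances; a label with a single member gets NaN (silhouette
    undefined). Intended for the first three principal-component scores.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct labels")
    sil = silhouette_samples(X, labels)
    out: dict[str, float] = {}
    for lab in uniq:
        mask = labels == lab
        out[str(lab)] = (float(np.mean(sil[mask])) if mask.sum() > 1
                         else float("nan"))
    return out
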