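"""Synthetic recordings: alarm calls, marker kinematics and soma masks.

Every downstream stage of the pipeline is exercised against data produced
here, with known ground truth. Three generators emulate the three data
streams of the study:

* :func:`synth_call` / :func:`synth_call_dataset` — WAV alarm calls of the
  three types (type 1 sinusoidal, type 3 irregular pulse train, type 2 a
  blend of both), calibrated so that the population has its spectral peak
  near 1 kHz and the bulk of its power between 500 Hz and 5 kHz.
* :func:`synth_kinematic_sequence` — per-frame 2-D marker coordinates for
  the five head markers (jaw extremities and larynx), with larynx excursion
  events whose amplitude and cycle duration follow configurable
  distributions per behavior (breathing vs vocalization) and view.
* :func:`synth_soma_masks` — labeled raster masks of elliptical somata with
  an analytic ground-truth table of axes and areas.

Event amplitudes, cycle durations and soma diameters are drawn from gamma
distributions parameterized by mean and s.d.: positive support with the
configured first two moments exactly, so recovery tests compare against the
configured values without truncation bias.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .audio import CALL_TYPES, AudioClip
from .kinematics import MARKERS, MarkerTrack

__all__ = [
    "SynthCallParams",
    "SynthKinParams",
    "SynthSomaParams",
    "synth_call",
    "synth_call_dataset",
    "synth_kinematic_sequence",
    "synth_soma_masks",
    "kinematic_defaults",
    "KINEMATIC_CELLS",
    "SOMA_DEFAULTS",
    "SynthKinResult",
    "SynthSomaResult",
]


# --------------------------------------------------------------------------
# Parameter blocks
# --------------------------------------------------------------------------

@dataclass
class SynthCallParams:
    """Waveform-model parameters for one synthetic alarm call."""

    call_type: str = "type1"
    duration_s: float = 0.3
    carrier_hz: float = 1000.0   # population peak frequency target
    n_harmonics: int = 4
    harmonic_rolloff_db: float = 6.0
    am_rate_hz: float = 25.0     # type-1 envelope modulation
    pulse_rate_hz: float = 20.0  # type-3 mean pulse rate
    pulse_jitter_cv: float = 0.4  # cv of inter-pulse intervals
    pulse_decay_s: float = 0.012  # per-pulse exponential decay
    pulse_rolloff_db: float = 3.0  # shallower: impulsive excitation is broadband
    mix_fraction: float = 0.5    # type-2: weight of the sinusoidal component
    snr_db: float | None = 25.0  # broadband noise floor; None = noiseless
    sample_rate_hz: float = 44100.0
    seed: int = 0

    def validate(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"call_type must be one of {CALL_TYPES}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if not 0.0 <= self.mix_fraction <= 1.0:
            raise ValueError("mix_fraction must lie in [0, 1]")
        if self.pulse_rate_hz <= 0 or self.pulse_jitter_cv < 0:
            raise ValueError("pulse parameters must be non-negative")


@dataclass
class SynthKinParams:
    """Event-population parameters for one synthetic marker sequence."""

    behavior: Literal["breathing", "vocalization"] = "vocalization"
    view: Literal["lateral", "dorsal"] = "dorsal"
    mean_displacement_cm: float = 0.54
    sd_displacement_cm: float = 0.40
    mean_cycle_s: float = 0.89
    sd_cycle_s: float = 0.31
    n_events: int = 10
    frame_rate_hz: float = 200.0
    noise_cm: float = 0.01
    gape_gain: float = 0.3   # gape excursion as a fraction of larynx amplitude
    individual_id: str = "synth"
    seed: int = 0

    def validate(self) -> None:
        if self.behavior not in ("breathing", "vocalization"):
            raise ValueError("behavior must be breathing or vocalization")
        if self.view not in ("lateral", "dorsal"):
            raise ValueError("view must be lateral or dorsal")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 200.0 <= self.frame_rate_hz <= 400.0:
            raise ValueError("frame_rate_hz must lie in [200, 400]")
        if self.noise_cm < 0:
            raise ValueError("noise_cm must be non-negative")
        if self.mean_displacement_cm <= 0 or self.mean_cycle_s <= 0:
            raise ValueError("means must be positive")


# Per behavior x axis displacement (cm) and cycle-duration (s) populations.
# Antero-posterior displacements live in the dorsal view, dorso-ventral in
# the lateral view, matching how the distance signals are defined.
KINEMATIC_CELLS: dict[tuple[str, str], dict[str, float]] = {
    ("vocalization", "dorsal"): dict(mean_displacement_cm=0.54, sd_displacement_cm=0.40,
                                     mean_cycle_s=0.89, sd_cycle_s=0.31),
    ("breathing", "dorsal"): dict(mean_displacement_cm=0.06, sd_displacement_cm=0.03,
                                  mean_cycle_s=1.28, sd_cycle_s=0.38),
    ("vocalization", "lateral"): dict(mean_displacement_cm=0.80, sd_displacement_cm=0.71,
                                      mean_cycle_s=0.70, sd_cycle_s=0.36),
    ("breathing", "lateral"): dict(mean_displacement_cm=0.26, sd_displacement_cm=0.14,
                                   mean_cycle_s=0.93, sd_cycle_s=0.18),
}


def kinematic_defaults(behavior: str, view: str, **overrides) -> SynthKinParams:
    """SynthKinParams for one behavior x view cell at the calibrated defaults."""
    try:
        cell = KINEMATIC_CELLS[(behavior, view)]
    except KeyError:
        raise ValueError(f"no defaults for behavior={behavior!r}, view={view!r}")
    kwargs = dict(behavior=behavior, view=view, **cell)
    kwargs.update(overrides)
    return SynthKinParams(**kwargs)


@dataclass
class SynthSomaParams:
    """Population parameters for synthetic elliptical soma masks."""

    n_somata: int = 73
    mean_min_diam_um: float = 18.1
    sd_min_diam_um: float = 9.4    # sem 1.1 um x sqrt(73)
    mean_axis_ratio: float = 1.85  # max/min diameter
    sd_axis_ratio: float = 0.35
    um_per_px: float = 0.5
    image_size_px: int = 1280
    seed: int = 0

    def validate(self) -> None:
        if self.n_somata < 1:
            raise ValueError("n_somata must be >= 1")
        if self.um_per_px <= 0 or self.image_size_px < 8:
            raise ValueError("invalid raster geometry")
        if self.mean_min_diam_um <= 0 or self.mean_axis_ratio < 1.0:
            raise ValueError("diameters must be positive and axis ratio >= 1")


SOMA_DEFAULTS = SynthSomaParams()


def _gamma_mean_sd(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Gamma draw with the given mean and s.d.; degenerate at sd == 0."""
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)


# --------------------------------------------------------------------------
# Alarm calls
# --------------------------------------------------------------------------

def _harmonic_stack(t: np.ndarray, params: SynthCallParams,
                    phases: np.ndarray, rolloff_db: float) -> np.ndarray:
    """Sum of n_harmonics partials with the given dB-per-harmonic roll-off."""
    x = np.zeros_like(t)
    nyq = params.sample_rate_hz / 2
    for h in range(1, params.n_harmonics + 1):
        f = h * params.carrier_hz
        if f >= nyq:
            break
        amp = 10.0 ** (-(h - 1) * rolloff_db / 20.0)
        x += amp * np.sin(2 * np.pi * f * t + phases[h - 1])
    return x


def _sinusoidal_component(t: np.ndarray, params: SynthCallParams,
                          rng: np.random.Generator) -> np.ndarray:
    phases = rng.uniform(0, 2 * np.pi, size=params.n_harmonics)
    x = _harmonic_stack(t, params, phases, params.harmonic_rolloff_db)
    # amplitude modulation: raised-cosine envelope, 90% depth
    depth = 0.9
    env = (1 - depth) + depth * 0.5 * (1 - np.cos(2 * np.pi * params.am_rate_hz * t))
    return x * env


def _pulse_train_component(t: np.ndarray, params: SynthCallParams,
                           rng: np.random.Generator) -> np.ndarray:
    fs = params.sample_rate_hz
    mean_ipi = 1.0 / params.pulse_rate_hz
    cv = params.pulse_jitter_cv
    # first pulse half an interval in, so every pulse is an interior
    # envelope maximum; gamma-distributed inter-pulse intervals
    times = [0.5 * mean_ipi]
    while times[-1] < params.duration_s:
        ipi = mean_ipi if cv == 0 else _gamma_mean_sd(rng, mean_ipi, cv * mean_ipi)
        times.append(times[-1] + max(ipi, 2.0 / fs))
    pulse_times = [pt for pt in times if pt < params.duration_s]

    x = np.zeros_like(t)
    for pt in pulse_times:
        i0 = int(np.ceil(pt * fs))
        if i0 >= t.size:
            continue
        tau = t[i0:] - pt
        # keep the per-pulse kernel short: 8 decay constants
        n_k = min(tau.size, int(8 * params.pulse_decay_s * fs))
        tau = tau[:n_k]
        phases = rng.uniform(0, 2 * np.pi, size=params.n_harmonics)
        kern = np.exp(-tau / params.pulse_decay_s) * _harmonic_stack(
            tau, params, phases, params.pulse_rolloff_db
        )
        x[i0 : i0 + n_k] += kern
    return x


def synth_call(params: SynthCallParams) -> AudioClip:
    """Synthesize one alarm call of the requested type.

    Type 1 is an amplitude-modulated harmonic stack, type 3 a train of
    exponentially decaying tone pulses at irregular intervals, and type 2 a
    ``mix_fraction``-weighted blend of both. The peak absolute amplitude is
    normalized to 1 before broadband noise is injected at ``snr_db``, then
    re-normalized. Identical parameters and seed give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate_hz
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs

    def _unit(x: np.ndarray) -> np.ndarray:
        peak = np.max(np.abs(x))
        return x / peak if peak > 0 else x

    if params.call_type == "type1":
        x = _unit(_sinusoidal_component(t, params, rng))
    elif params.call_type == "type3":
        x = _unit(_pulse_train_component(t, params, rng))
    else:  # type2: blend of both components at matched RMS power
        def _unit_rms(y: np.ndarray) -> np.ndarray:
            rms = np.sqrt(np.mean(y**2))
            return y / rms if rms > 0 else y

        sin_part = _unit_rms(_sinusoidal_component(t, params, rng))
        pul_part = _unit_rms(_pulse_train_component(t, params, rng))
        x = params.mix_fraction * sin_part + (1 - params.mix_fraction) * pul_part

    # fade edges (10 ms raised cosine) to avoid onset/offset clicks
    n_fade = min(int(0.01 * fs), n // 4)
    if n_fade > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        x[:n_fade] *= ramp
        x[-n_fade:] *= ramp[::-1]

    x = _unit(x)
    if params.snr_db is not None:
        sig_power = np.mean(x**2)
        noise_sd = np.sqrt(sig_power * 10.0 ** (-params.snr_db / 10.0))
        x = _unit(x + rng.normal(0.0, noise_sd, size=n))

    return AudioClip(
        samples=x,
        sample_rate_hz=fs,
        call_type=params.call_type,
        source=f"synth(seed={params.seed})",
    )


def synth_call_dataset(
    n_per_type: int,
    n_individuals: int,
    seed: int = 0,
    snr_db: float | None = 25.0,
) -> list[AudioClip]:
    """Labeled synthetic call population: ``n_per_type`` calls of each of the
    three types for each of ``n_individuals`` animals.

    Each individual carries a small random perturbation of the default
    carrier, modulation and pulse rates (s.d. 10 Hz on the 1 kHz carrier);
    each call additionally jitters the carrier by 5 Hz and its duration
    uniformly in 0.1-0.6 s. Deterministic under a fixed seed.
    """
    if n_per_type < 1 or n_individuals < 1:
        raise ValueError("n_per_type and n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    clips: list[AudioClip] = []
    for i in range(n_individuals):
        ind = f"ind{i + 1}"
        ind_carrier = 1000.0 + rng.normal(0.0, 10.0)
        ind_am = 25.0 * float(np.exp(rng.normal(0.0, 0.1)))
        ind_pulse = 20.0 * float(np.exp(rng.normal(0.0, 0.1)))
        for call_type in CALL_TYPES:
            for k in range(n_per_type):
                params = SynthCallParams(
                    call_type=call_type,
                    duration_s=float(rng.uniform(0.1, 0.6)),
                    carrier_hz=ind_carrier + rng.normal(0.0, 5.0),
                    am_rate_hz=ind_am,
                    pulse_rate_hz=ind_pulse,
                    mix_fraction=float(rng.uniform(0.15, 0.85)),
                    snr_db=snr_db,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                clip = synth_call(params)
                clip.individual_id = ind
                clip.source = f"{ind}_{call_type}_{k}"
                clips.append(clip)
    return clips


# --------------------------------------------------------------------------
# Marker kinematics
# --------------------------------------------------------------------------

# Resting marker positions (cm) per view. In the dorsal view x is the
# antero-posterior axis; in the lateral view y is the dorso-ventral axis.
_BASE_POSITIONS = {
    "dorsal": {
        "upper_jaw_anterior": (4.0, 0.3),
        "upper_jaw_posterior": (0.5, 0.9),
        "lower_jaw_anterior": (4.0, -0.3),
        "lower_jaw_posterior": (0.5, -0.9),
        "larynx": (1.0, 0.0),
    },
    "lateral": {
        "upper_jaw_anterior": (4.0, 1.0),
        "upper_jaw_posterior": (0.5, 1.2),
        "lower_jaw_anterior": (4.0, 0.6),
        "lower_jaw_posterior": (0.5, 0.0),
        "larynx": (1.0, 0.2),
    },
}

# Reference marker whose distance to the larynx defines each view's signal.
_LARYNX_REF = {"dorsal": "lower_jaw_anterior", "lateral": "upper_jaw_posterior"}


@dataclass
class SynthKinResult:
    """Generated marker track plus the ground-truth event table."""

    track: MarkerTrack
    events: pd.DataFrame = field(repr=False)  # onset_s, amplitude_cm, duration_s


def synth_kinematic_sequence(params: SynthKinParams) -> SynthKinResult:
    """Generate a marker sequence containing ``n_events`` larynx excursions.

    Each event displaces the larynx marker along the line away from the
    view's reference jaw marker by a half-sine (single smooth excursion
    returning to baseline) whose peak amplitude and duration are drawn from
    gamma distributions with the configured mean and s.d. The anterior
    upper-jaw marker makes a coupled gape excursion of ``gape_gain`` times
    the larynx amplitude. Gaussian jitter of s.d. ``noise_cm`` is added to
    every coordinate.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.frame_rate_hz
    dt = 1.0 / fs

    amps = _gamma_mean_sd(rng, params.mean_displacement_cm,
                          params.sd_displacement_cm, size=params.n_events)
    durs = _gamma_mean_sd(rng, params.mean_cycle_s, params.sd_cycle_s,
                          size=params.n_events)
    durs = np.maximum(durs, 6 * dt)
    gaps = rng.uniform(0.6, 1.0, size=params.n_events + 1)

    onsets = np.empty(params.n_events)
    t_cursor = gaps[0]
    for i in range(params.n_events):
        onsets[i] = t_cursor
        t_cursor += durs[i] + gaps[i + 1]
    total_s = t_cursor + 0.5
    n_frames = int(np.ceil(total_s * fs))
    t = np.arange(n_frames) * dt

    base = _BASE_POSITIONS[params.view]
    ref = np.array(base[_LARYNX_REF[params.view]])
    lar0 = np.array(base["larynx"])
    away = (lar0 - ref) / np.linalg.norm(lar0 - ref)  # unit: away from ref

    # jaw coordination is loose: each event's gape excursion has its own
    # random gain (mean = gape_gain) and onset offset, so jaw and larynx
    # are only partially correlated, with event-to-event variation
    gape_gains = params.gape_gain * rng.uniform(0.0, 2.0, size=params.n_events)
    gape_shifts = rng.uniform(-0.3, 0.3, size=params.n_events) * durs

    lar_excursion = np.zeros(n_frames)
    gape_excursion = np.zeros(n_frames)
    for onset, amp, dur, g_gain, g_shift in zip(onsets, amps, durs,
                                                gape_gains, gape_shifts):
        sl = (t >= onset) & (t < onset + dur)
        lar_excursion[sl] += amp * np.sin(np.pi * (t[sl] - onset) / dur)
        g_on = onset + g_shift
        gl = (t >= g_on) & (t < g_on + dur)
        gape_excursion[gl] += g_gain * amp * np.sin(np.pi * (t[gl] - g_on) / dur)

    coords = np.empty((n_frames, len(MARKERS), 2))
    uja_dir = np.array([0.0, 1.0])  # gape opens the anterior upper-jaw marker
    for m, name in enumerate(MARKERS):
        pos = np.tile(np.array(base[name]), (n_frames, 1))
        if name == "larynx":
            pos += np.outer(lar_excursion, away)
        elif name == "upper_jaw_anterior":
            pos += np.outer(gape_excursion, uja_dir)
        coords[:, m, :] = pos
    if params.noise_cm > 0:
        coords = coords + rng.normal(0.0, params.noise_cm, size=coords.shape)

    track = MarkerTrack(
        view=params.view,
        frame_rate_hz=fs,
        coords_cm=coords,
        individual_id=params.individual_id,
    )
    truth = pd.DataFrame(
        {"onset_s": onsets, "amplitude_cm": amps, "duration_s": durs}
    )
    return SynthKinResult(track=track, events=truth)


# --------------------------------------------------------------------------
# Soma masks
# --------------------------------------------------------------------------

@dataclass
class SynthSomaResult:
    """Labeled mask image and analytic ground truth for each ellipse."""

    labels: np.ndarray          # uint16 label raster, 0 = background
    truth: pd.DataFrame = field(repr=False)
    um_per_px: float = 1.0


def synth_soma_masks(params: SynthSomaParams) -> SynthSomaResult:
    """Draw non-overlapping filled rotated ellipses as a label raster.

    Minor diameters are gamma-distributed at the configured mean/s.d.; the
    major axis is minor x axis-ratio (ratio >= 1). The ground-truth table
    records each ellipse's analytic axes (um) and area pi*a*b/4 (um^2).
    Placement is by rejection sampling on bounding circles; a capacity error
    is raised if a region cannot be placed after bounded retries.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    size = params.image_size_px
    scale = params.um_per_px

    min_d = np.empty(params.n_somata)
    for i in range(params.n_somata):
        d = _gamma_mean_sd(rng, params.mean_min_diam_um, params.sd_min_diam_um)
        while d < 2.0 * scale:  # at least 2 px across
            d = _gamma_mean_sd(rng, params.mean_min_diam_um, params.sd_min_diam_um)
        min_d[i] = d
    ratio = 1.0 + np.maximum(
        _gamma_mean_sd(rng, params.mean_axis_ratio - 1.0, params.sd_axis_ratio,
                       size=params.n_somata),
        0.0,
    )
    max_d = min_d * ratio
    theta = rng.uniform(0.0, np.pi, size=params.n_somata)

    labels = np.zeros((size, size), dtype=np.uint16)
    centers = np.full((params.n_somata, 2), np.nan)
    radii_px = max_d / 2.0 / scale
    # place largest regions first: packing succeeds far more often when
    # the big bounding circles go in before the image gets crowded
    for rank, i in enumerate(np.argsort(-radii_px)):
        r_bound = radii_px[i] + 2.0
        if 2 * (r_bound + 1) >= size:
            raise RuntimeError(
                f"region {i + 1}/{params.n_somata} cannot be placed: "
                f"bounding diameter exceeds image_size_px={size}"
            )
        done = ~np.isnan(centers[:, 0])
        placed = False
        for _ in range(10000):
            c = rng.uniform(r_bound + 1, size - r_bound - 1, size=2)
            if rank == 0 or np.all(
                np.hypot(*(centers[done] - c).T)
                > radii_px[done] + r_bound + 2.0
            ):
                centers[i] = c
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place region {i + 1}/{params.n_somata}; "
                "increase image_size_px"
            )
        # rasterize at radius - 0.5 px: boundary-inclusive filling plus the
        # pixel-extent (corner) measurement convention otherwise inflate
        # measured diameters by about one pixel relative to the truth table
        rr, cc = draw_ellipse(
            centers[i, 0],
            centers[i, 1],
            max(max_d[i] / 2.0 / scale - 0.5, 1.0),
            max(min_d[i] / 2.0 / scale - 0.5, 1.0),
            shape=labels.shape,
            rotation=theta[i],
        )
        labels[rr, cc] = i + 1

    truth = pd.DataFrame(
        {
            "label": np.arange(1, params.n_somata + 1, dtype=int),
            "min_diam_um": min_d,
            "max_diam_um": max_d,
            "area_um2": np.pi * min_d * max_d / 4.0,
        }
    )
    return SynthSomaResult(labels=labels, truth=truth, um_per_px=scale)
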