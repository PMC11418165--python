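"""Laryngeal and jaw kinematics from tracked marker coordinates.

Five subcutaneous radio-opaque markers are tracked in high-speed X-ray
video (200-400 frames/s): the anterior and posterior extremities of the
upper and lower jaws, and one marker next to the laryngeal cartilages.
From the per-frame 2-D coordinates three distance signals are derived:

* **gape** — distance between the two anterior jaw markers (both views);
* **antero-posterior larynx displacement** — distance between the larynx
  marker and the anterior lower-jaw marker, defined in the dorsal view;
* **dorso-ventral larynx displacement** — distance between the posterior
  upper-jaw marker and the larynx marker, defined in the lateral view.

Movement events (one excursion returning to baseline) are extracted from
each larynx signal; per event the total movement (max minus min of the
distance within the event) and the cycle duration (excursion onset to
return to baseline) are measured. Behaviors (breathing vs vocalization)
are contrasted with a one-way fixed-effect linear model on the log10
response, and jaw-larynx coordination is summarized by the R-squared of an
ordinary least-squares regression of the larynx signal on the gape signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

MARKERS = (
    "upper_jaw_anterior",
    "upper_jaw_posterior",
    "lower_jaw_anterior",
    "lower_jaw_posterior",
    "larynx",
)

__all__ = [
    "MARKERS",
    "MarkerTrack",
    "KinematicSeries",
    "MovementEvent",
    "smooth_track",
    "compute_series",
    "extract_events",
    "compare_behaviors",
    "jaw_larynx_coupling",
    "read_track_csv",
    "write_track_csv",
    "events_to_frame",
    "BehaviorContrast",
]


@dataclass
class MarkerTrack:
    """Per-frame 2-D coordinates (cm) of the five head markers in one view."""

    view: str                      # "lateral" | "dorsal"
    frame_rate_hz: float
    coords_cm: np.ndarray          # (n_frames, 5, 2), marker order = MARKERS
    individual_id: str = ""

    def __post_init__(self) -> None:
        self.coords_cm = np.asarray(self.coords_cm, dtype=float)
        if self.view not in ("lateral", "dorsal"):
            raise ValueError("view must be 'lateral' or 'dorsal'")
        if not 200.0 <= self.frame_rate_hz <= 400.0:
            raise ValueError("frame_rate_hz must lie in [200, 400]")
        if self.coords_cm.ndim != 3 or self.coords_cm.shape[1:] != (len(MARKERS), 2):
            raise ValueError("coords_cm must have shape (n_frames, 5, 2)")
        if not np.all(np.isfinite(self.coords_cm)):
            raise ValueError("coordinates must be finite (interpolate gaps first)")

    @property
    def n_frames(self) -> int:
        return self.coords_cm.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def marker(self, name: str) -> np.ndarray:
        return self.coords_cm[:, MARKERS.index(name), :]


@dataclass
class KinematicSeries:
    """The three derived distance signals for one marker sequence."""

    time_s: np.ndarray
    gape_cm: np.ndarray
    larynx_cm: np.ndarray          # view-specific larynx distance signal
    axis: str                      # "antero_posterior" | "dorso_ventral"
    view: str
    frame_rate_hz: float
    individual_id: str = ""

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class MovementEvent:
    """One extracted excursion of the larynx distance signal."""

    behavior: str                  # "breathing" | "vocalization"
    axis: str
    total_movement_cm: float
    cycle_duration_s: float
    onset_s: float
    individual_id: str = ""
    view: str = ""


# --------------------------------------------------------------------------
# Signal derivation
# --------------------------------------------------------------------------

def smooth_track(track: MarkerTrack, cutoff_hz: float = 10.0,
                 order: int = 4) -> MarkerTrack:
    """Zero-phase low-pass Butterworth smoothing of every coordinate.

    Defaults (10 Hz, order 4) pass the 1-2 Hz movement events untouched
    while removing frame-to-frame tracking jitter.
    """
    nyq = track.frame_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError("cutoff_hz must lie in (0, frame_rate/2)")
    sos = sps.butter(order, cutoff_hz, btype="lowpass", fs=track.frame_rate_hz,
                     output="sos")
    flat = track.coords_cm.reshape(track.n_frames, -1)
    smoothed = sps.sosfiltfilt(sos, flat, axis=0).reshape(track.coords_cm.shape)
    return replace(track, coords_cm=smoothed)


def compute_series(track: MarkerTrack) -> KinematicSeries:
    """Derive gape and the view-appropriate larynx distance signal.

    The dorsal view yields the antero-posterior larynx signal (larynx to
    anterior lower-jaw marker); the lateral view yields the dorso-ventral
    signal (posterior upper-jaw marker to larynx).
    """
    def dist(a: str, b: str) -> np.ndarray:
        return np.linalg.norm(track.marker(a) - track.marker(b), axis=1)

    gape = dist("upper_jaw_anterior", "lower_jaw_anterior")
    if track.view == "dorsal":
        larynx = dist("larynx", "lower_jaw_anterior")
        axis = "antero_posterior"
    else:
        larynx = dist("upper_jaw_posterior", "larynx")
        axis = "dorso_ventral"
    return KinematicSeries(
        time_s=track.times_s,
        gape_cm=gape,
        larynx_cm=larynx,
        axis=axis,
        view=track.view,
        frame_rate_hz=track.frame_rate_hz,
        individual_id=track.individual_id,
    )


# --------------------------------------------------------------------------
# Event extraction
# --------------------------------------------------------------------------

def _flank_time(x: np.ndarray, peak: int, level: float, direction: int) -> float:
    """Fractional index where x, walked from ``peak`` in ``direction``
    (-1 left, +1 right), first crosses below ``level`` (linear interp).
    Returns the series edge if the signal never comes back down."""
    i = peak
    last = x.size - 1
    while 0 < i < last:
        j = i + direction
        if x[j] < level:
            # interpolate between i (>= level) and j (< level)
            frac = (x[i] - level) / (x[i] - x[j])
            return i + direction * frac
        i = j
    return float(i)


def extract_events(
    series: KinematicSeries,
    behavior: str,
    min_prominence_cm: float = 0.02,
    baseline_percentile: float = 20.0,
) -> list[MovementEvent]:
    """Detect larynx excursions and measure total movement and duration.

    Candidate excursions are peaks of the larynx distance signal with
    prominence of at least ``min_prominence_cm``. The resting baseline is
    the ``baseline_percentile`` of the whole signal (the larynx sits at its
    resting distance between events, so a low percentile is robust to the
    events themselves). For each peak the onset and offset are found by
    walking down each flank to a small threshold above baseline and
    linearly extrapolating the flank to the baseline itself, which removes
    the threshold-height bias; cycle duration is offset minus onset. Total
    movement is the event's peak height above its baseline — the peak from
    a local quadratic fit (robust to residual tracking noise, exact for a
    smooth excursion) and the baseline from the median of the signal
    outside all event windows; for a single excursion returning to
    baseline this equals the max - min of the underlying movement.

    Windows that overlap are merged (one excursion, one event), and events
    whose peak rises less than ``min_prominence_cm`` above baseline are
    discarded as baseline noise. Events are returned sorted by onset.
    """
    if len(series) < 3:
        raise ValueError("series must contain at least 3 samples")
    x = np.asarray(series.larynx_cm, dtype=float)
    dt = 1.0 / series.frame_rate_hz
    if np.ptp(x) == 0:
        return []
    base = float(np.percentile(x, baseline_percentile))
    peaks, _ = sps.find_peaks(x, prominence=min_prominence_cm)
    peaks = [p for p in peaks if x[p] - base >= min_prominence_cm]
    if not peaks:
        return []

    windows: list[tuple[float, float]] = []
    for p in peaks:
        amp = x[p] - base
        h = max(0.05 * amp, 0.3 * min_prominence_cm)
        # crossing times at base+h and base+2h; the line through them
        # extended to the baseline estimates the true onset/offset
        t_h_l = _flank_time(x, p, base + h, -1)
        t_2h_l = _flank_time(x, p, base + 2 * h, -1)
        t_h_r = _flank_time(x, p, base + h, +1)
        t_2h_r = _flank_time(x, p, base + 2 * h, +1)
        onset = t_h_l - (t_2h_l - t_h_l)
        offset = t_h_r + (t_h_r - t_2h_r)
        windows.append((onset, offset))

    windows.sort()
    merged = [list(windows[0])]
    for a, b in windows[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    # refined baseline: median of the signal outside all event windows is
    # unbiased under symmetric tracking noise (a low percentile is not)
    outside = np.ones(x.size, dtype=bool)
    for a, b in merged:
        outside[max(int(a) - 10, 0) : min(int(b) + 11, x.size)] = False
    base_ref = float(np.median(x[outside])) if outside.any() else base

    events: list[MovementEvent] = []
    for a, b in merged:
        i0 = max(int(np.floor(a)), 0)
        i1 = min(int(np.ceil(b)) + 1, x.size)
        seg = x[i0:i1]
        # peak height from a local quadratic fit (robust to residual noise;
        # exact for a smooth single excursion): total movement = denoised
        # peak minus event baseline == max - min for one excursion
        p = i0 + int(np.argmax(seg))
        w = max(int(0.12 * (b - a)), 3)
        lo, hi = max(0, p - w), min(x.size, p + w + 1)
        tt = np.arange(lo, hi, dtype=float) - p
        c2, c1, c0 = np.polyfit(tt, x[lo:hi], 2)
        peak_val = c0 - c1 * c1 / (4 * c2) if c2 < 0 else float(x[p])
        events.append(
            MovementEvent(
                behavior=behavior,
                axis=series.axis,
                total_movement_cm=float(max(peak_val - base_ref, 0.0)),
                cycle_duration_s=float((b - a) * dt),
                onset_s=float(a * dt),
                individual_id=series.individual_id,
                view=series.view,
            )
        )
    return events


def events_to_frame(events: list[MovementEvent]) -> pd.DataFrame:
    """Tidy event table: one row per extracted movement event."""
    return pd.DataFrame(
        {
            "individual": [e.individual_id for e in events],
            "view": [e.view for e in events],
            "behavior": [e.behavior for e in events],
            "axis": [e.axis for e in events],
            "total_movement_cm": [e.total_movement_cm for e in events],
            "cycle_duration_s": [e.cycle_duration_s for e in events],
            "onset_s": [e.onset_s for e in events],
        }
    )


# --------------------------------------------------------------------------
# Statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorContrast:
    """One-way fixed-effect contrast of a log10 response between behaviors."""

    response: str
    F: float
    df: tuple[int, int]
    p: float
    group_means: dict[str, float]   # untransformed means per behavior
    group_sds: dict[str, float]
    n: dict[str, int]


def compare_behaviors(events: list[MovementEvent],
                      response: str = "displacement") -> BehaviorContrast:
    """Test breathing vs vocalization on log10-transformed responses.

    The model is a one-way fixed-effect linear model with behavior as the
    only factor, equivalent to a one-way ANOVA: F with (1, n-2) degrees of
    freedom. Group means and s.d. are reported on the original scale.
    """
    if response not in ("displacement", "duration"):
        raise ValueError("response must be 'displacement' or 'duration'")
    key = "total_movement_cm" if response == "displacement" else "cycle_duration_s"
    groups: dict[str, list[float]] = {}
    for e in events:
        groups.setdefault(e.behavior, []).append(getattr(e, key))
    if set(groups) != {"breathing", "vocalization"}:
        raise ValueError("events must contain both behaviors")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least 2 events per behavior")
    logs = {b: np.log10(np.asarray(v)) for b, v in groups.items()}
    F, p = stats.f_oneway(logs["breathing"], logs["vocalization"])
    n_total = sum(len(v) for v in groups.values())
    return BehaviorContrast(
        response=response,
        F=float(F),
        df=(1, n_total - 2),
        p=float(p),
        group_means={b: float(np.mean(v)) for b, v in groups.items()},
        group_sds={b: float(np.std(v, ddof=1)) for b, v in groups.items()},
        n={b: len(v) for b, v in groups.items()},
    )


def jaw_larynx_coupling(series: KinematicSeries) -> float:
    """R-squared of OLS regression of the larynx signal on the gape signal.

    Returns NaN (flagged by the caller) when the gape signal has zero
    variance, where the regression is undefined.
    """
    if len(series) < 3:
        raise ValueError("series must contain at least 3 samples")
    g = np.asarray(series.gape_cm)
    l = np.asarray(series.larynx_cm)
    if np.ptp(g) == 0 or np.allclose(np.var(g), 0.0):
        return float("nan")
    res = stats.linregress(g, l)
    return float(res.rvalue**2)


# --------------------------------------------------------------------------
# CSV interchange
# --------------------------------------------------------------------------

def write_track_csv(path: str | Path, track: MarkerTrack) -> None:
    """Long-format marker CSV: ``frame,time_s,marker,x_cm,y_cm,view``."""
    n = track.n_frames
    rows = []
    for m, name in enumerate(MARKERS):
        rows.append(
            pd.DataFrame(
                {
                    "frame": np.arange(n),
                    "time_s": track.times_s,
                    "marker": name,
                    "x_cm": track.coords_cm[:, m, 0],
                    "y_cm": track.coords_cm[:, m, 1],
                    "view": track.view,
                }
            )
        )
    pd.concat(rows).sort_values(["frame", "marker"]).to_csv(path, index=False)


def read_track_csv(path: str | Path, frame_rate_hz: float,
                   individual_id: str = "") -> MarkerTrack:
    """Read a long-format marker CSV written by :func:`write_track_csv`."""
    df = pd.read_csv(path)
    views = df["view"].unique()
    if len(views) != 1:
        raise ValueError("track CSV must contain exactly one view")
    n = int(df["frame"].max()) + 1
    coords = np.full((n, len(MARKERS), 2), np.nan)
    for m, name in enumerate(MARKERS):
        sub = df[df["marker"] == name].sort_values("frame")
        coords[sub["frame"].to_numpy(), m, 0] = sub["x_cm"].to_numpy()
        coords[sub["frame"].to_numpy(), m, 1] = sub["y_cm"].to_numpy()
    # linear interpolation over any missing frames, per marker/coordinate
    for m in range(len(MARKERS)):
        for c in range(2):
            col = coords[:, m, c]
            bad = np.isnan(col)
            if bad.any():
                idx = np.arange(n)
                coords[:, m, c] = np.interp(idx, idx[~bad], col[~bad])
    return MarkerTrack(
        view=str(views[0]),
        frame_rate_hz=frame_rate_hz,
        coords_cm=coords,
        individual_id=individual_id,
    )
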