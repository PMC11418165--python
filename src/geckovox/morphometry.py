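"""Soma morphometry from labeled raster masks.

Retrogradely labeled motoneuron somata arrive as 2-D labeled masks with a
known µm-per-pixel scale. Per region the minimal and maximal soma
diameters are measured as the minimum and maximum Feret (caliper)
diameters of the region's convex hull, and the surface area as the pixel
count times the squared scale. Each pixel is treated as a unit square, so
the hull is taken over pixel corners and a w-pixel-wide region measures w
pixels across; calipers are evaluated at 1-degree rotation steps.

Summaries report minimum, maximum, mean and s.e.m. (sample s.d. / sqrt(n))
per metric, and histograms use fixed-width bins anchored at zero
(left-closed, right-open; diameters default to 5 µm bins, areas 100 µm²).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

__all__ = [
    "SomaMeasurement",
    "MorphometrySummary",
    "measure_soma",
    "summarize",
    "summarize_all",
    "histogram",
    "feret_diameters",
    "read_label_png",
    "write_label_png",
]

DIAMETER_BIN_UM = 5.0   # figure convention; 4 µm also in circulation
AREA_BIN_UM2 = 100.0


@dataclass(frozen=True)
class SomaMeasurement:
    label: int
    min_diam_um: float
    max_diam_um: float
    area_um2: float
    degenerate: bool = False   # single-pixel region: diameters = pixel pitch


@dataclass(frozen=True)
class MorphometrySummary:
    metric: str
    n: int
    minimum: float
    maximum: float
    mean: float
    sem: float
    sem_defined: bool          # False when n == 1 (sem reported as 0)


def feret_diameters(coords_px: np.ndarray, angle_step_deg: float = 1.0
                    ) -> tuple[float, float]:
    """Min and max Feret diameters (in pixels) of a set of pixel positions.

    Pixels are unit squares: the hull is built over the four corners of
    every pixel. The max Feret is the largest pairwise distance between
    hull vertices; the min Feret is the smallest projection width over
    rotations in ``angle_step_deg`` increments.
    """
    coords = np.asarray(coords_px, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords_px must be (n, 2)")
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    pts = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] > 2 and np.ptp(uniq[:, 0]) > 0 and np.ptp(uniq[:, 1]) > 0:
        hull_pts = uniq[ConvexHull(uniq).vertices]
    else:
        hull_pts = uniq
    diffs = hull_pts[:, None, :] - hull_pts[None, :, :]
    max_feret = float(np.sqrt((diffs**2).sum(-1)).max())
    angles = np.deg2rad(np.arange(0.0, 180.0, angle_step_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = hull_pts @ dirs.T                      # (points, angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    min_feret = float(widths.min())
    return min_feret, max_feret


def measure_soma(mask: np.ndarray, um_per_px: float) -> list[SomaMeasurement]:
    """Measure every labeled region: min/max Feret diameter and area.

    An empty mask yields an empty list. A single-pixel region is
    degenerate: both diameters are reported as one pixel pitch and the
    measurement is flagged.
    """
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels != 0]
    out: list[SomaMeasurement] = []
    for lab in labels:
        rr, cc = np.nonzero(mask == lab)
        area = rr.size * um_per_px**2
        if rr.size == 1:
            out.append(SomaMeasurement(int(lab), um_per_px, um_per_px,
                                       area, degenerate=True))
            continue
        mn, mx = feret_diameters(np.column_stack([rr, cc]))
        out.append(SomaMeasurement(int(lab), mn * um_per_px, mx * um_per_px,
                                   area))
    return out


_METRICS = ("min_diam_um", "max_diam_um", "area_um2")


def summarize(measurements: list[SomaMeasurement],
              metric: str = "min_diam_um") -> MorphometrySummary:
    """Minimum, maximum, mean and s.e.m. of one metric over the somata."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if not measurements:
        raise ValueError("no measurements to summarize")
    vals = np.array([getattr(m, metric) for m in measurements], dtype=float)
    n = vals.size
    sem_defined = n > 1
    sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if sem_defined else 0.0
    return MorphometrySummary(
        metric=metric,
        n=n,
        minimum=float(vals.min()),
        maximum=float(vals.max()),
        mean=float(vals.mean()),
        sem=sem,
        sem_defined=sem_defined,
    )


def summarize_all(measurements: list[SomaMeasurement]
                  ) -> dict[str, MorphometrySummary]:
    return {m: summarize(measurements, m) for m in _METRICS}


def histogram(measurements: list[SomaMeasurement], metric: str,
              bin_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width histogram with left-closed right-open bins anchored at 0.

    Returns (edges, counts) with len(edges) = len(counts) + 1; the counts
    sum to the number of measurements.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    vals = np.array([getattr(m, metric) for m in measurements], dtype=float)
    n_bins = int(np.floor(vals.max() / bin_size)) + 1 if vals.size else 1
    edges = np.arange(n_bins + 1) * bin_size
    idx = np.floor(vals / bin_size).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts


def measurements_to_frame(measurements: list[SomaMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [m.label for m in measurements],
            "min_diam_um": [m.min_diam_um for m in measurements],
            "max_diam_um": [m.max_diam_um for m in measurements],
            "area_um2": [m.area_um2 for m in measurements],
        }
    )


def write_label_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a label raster as 16-bit single-channel PNG."""
    import imageio.v3 as iio

    iio.imwrite(str(path), np.asarray(mask, dtype=np.uint16))


def read_label_png(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:  # collapse accidental channel axis
        arr = arr[..., 0]
    return arr.astype(np.uint16)
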