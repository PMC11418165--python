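#!/usr/bin/env python
"""Morphometry of the labeled motoneuron somata.

Reads the 16-bit label mask from 01, measures minimum/maximum Feret
diameters and areas per region, summarizes each metric (min, max, mean,
s.e.m.), compares against the generator's analytic ground truth, and
plots the three histograms (5 um diameter bins, 100 um^2 area bins).
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from geckovox import morphometry as morpho

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path,
                        default=ROOT / "results" / "data" / "somata")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    labels_png = args.data / "labels.png"
    if not labels_png.is_file():
        raise SystemExit(f"{labels_png} missing - run 01_synthesize_dataset.py")
    mask = morpho.read_label_png(labels_png)
    um_per_px = float((args.data / "scale.txt").read_text().strip())
    truth = pd.read_csv(args.data / "truth.csv")

    meas = morpho.measure_soma(mask, um_per_px)
    tables = args.out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    df = morpho.measurements_to_frame(meas)
    df.to_csv(tables / "soma_measurements.csv", index=False,
              float_format="%.6g")

    summary_rows = []
    units = {"min_diam_um": "um", "max_diam_um": "um", "area_um2": "um^2"}
    for metric, s in morpho.summarize_all(meas).items():
        summary_rows.append(
            {"metric": metric, "n": s.n, "min": s.minimum, "max": s.maximum,
             "mean": s.mean, "sem": s.sem,
             "truth_mean": truth[metric].mean()}
        )
        print(f"{metric}: mean {s.mean:.1f} {units[metric]} "
              f"(s.e.m. {s.sem:.1f}; range {s.minimum:.1f}-{s.maximum:.1f}; "
              f"n={s.n}; generator truth mean {truth[metric].mean():.1f})")
    pd.DataFrame(summary_rows).to_csv(tables / "soma_summary.csv",
                                      index=False, float_format="%.6g")

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    bins = {"min_diam_um": morpho.DIAMETER_BIN_UM,
            "max_diam_um": morpho.DIAMETER_BIN_UM,
            "area_um2": morpho.AREA_BIN_UM2}
    for ax, (metric, bin_size) in zip(axes, bins.items()):
        edges, counts = morpho.histogram(meas, metric, bin_size)
        ax.bar(edges[:-1], counts, width=bin_size, align="edge",
               edgecolor="k", linewidth=0.4)
        ax.set_xlabel(f"{metric} ({units[metric]})")
        ax.set_ylabel("count")
    fig.tight_layout()
    figdir = args.out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(figdir / "soma_histograms.png", dpi=150)


if __name__ == "__main__":
    main()
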