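#!/usr/bin/env python
"""Laryngeal kinematics: breathing vs vocalization.

Reads the marker-track CSVs from 01, smooths them (zero-phase Butterworth,
10 Hz), derives the gape and larynx distance signals, extracts movement
events, and runs the behavior contrast (one-way linear model on log10
responses, per axis) plus the jaw-larynx coupling regressions.

Writes results/tables/kinematic_events.csv, kinematic_stats.csv,
coupling.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from geckovox import kinematics as kin

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path,
                        default=ROOT / "results" / "data" / "kinematics")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    manifest = args.data / "manifest.csv"
    if not manifest.is_file():
        raise SystemExit(f"{manifest} missing - run 01_synthesize_dataset.py")
    mf = pd.read_csv(manifest)

    all_events: list[kin.MovementEvent] = []
    coupling_rows = []
    for row in mf.itertuples():
        stem = f"{row.behavior}_{row.view}"
        track = kin.read_track_csv(args.data / f"{stem}_track.csv",
                                   frame_rate_hz=row.frame_rate_hz,
                                   individual_id="synth")
        series = kin.compute_series(kin.smooth_track(track))
        events = kin.extract_events(series, row.behavior)
        all_events += events
        r2 = kin.jaw_larynx_coupling(series)
        coupling_rows.append((row.behavior, row.view, series.axis,
                              len(events), r2))
        print(f"{stem}: {len(events)} events "
              f"(generated {row.n_events}), coupling R^2 = {r2:.3f}")

    tables = args.out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    kin.events_to_frame(all_events).to_csv(
        tables / "kinematic_events.csv", index=False, float_format="%.6g")
    pd.DataFrame(coupling_rows, columns=["behavior", "view", "axis",
                                         "n_events", "r_squared"]).to_csv(
        tables / "coupling.csv", index=False, float_format="%.6g")

    stats_rows = []
    for axis in ("antero_posterior", "dorso_ventral"):
        axis_events = [e for e in all_events if e.axis == axis]
        for response in ("displacement", "duration"):
            c = kin.compare_behaviors(axis_events, response)
            stats_rows.append(
                {
                    "axis": axis,
                    "response": response,
                    "F": c.F,
                    "df1": c.df[0],
                    "df2": c.df[1],
                    "p": c.p,
                    "mean_breathing": c.group_means["breathing"],
                    "sd_breathing": c.group_sds["breathing"],
                    "mean_vocalization": c.group_means["vocalization"],
                    "sd_vocalization": c.group_sds["vocalization"],
                }
            )
            unit = "cm" if response == "displacement" else "s"
            print(
                f"{axis} {response}: F(1,{c.df[1]}) = {c.F:.1f}, "
                f"p = {c.p:.2g}; vocalization "
                f"{c.group_means['vocalization']:.2f} +/- "
                f"{c.group_sds['vocalization']:.2f} {unit} vs breathing "
                f"{c.group_means['breathing']:.2f} +/- "
                f"{c.group_sds['breathing']:.2f} {unit}"
            )
    pd.DataFrame(stats_rows).to_csv(tables / "kinematic_stats.csv",
                                    index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
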