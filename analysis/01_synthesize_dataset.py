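#!/usr/bin/env python
"""Generate the synthetic study dataset: alarm-call WAVs, marker-track
CSVs for breathing and vocalization in both camera views, and the labeled
soma mask with its ground-truth table.

Writes everything under results/data/; downstream scripts (02-05) read
from there. Deterministic under --seed.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from geckovox import morphometry as morpho
from geckovox import synth
from geckovox.audio import write_wav
from geckovox.kinematics import write_track_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "data")
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)
    out = args.out

    # --- alarm calls: 20 per type from each of 6 individuals -------------
    audio_dir = out / "audio"
    audio_dir.mkdir(parents=True, exist_ok=True)
    clips = synth.synth_call_dataset(n_per_type=20, n_individuals=6,
                                     seed=args.seed)
    rows = []
    for clip in clips:
        name = f"{clip.source}.wav"
        write_wav(audio_dir / name, clip)
        rows.append((name, clip.individual_id, clip.call_type,
                     round(clip.duration_s, 4)))
    pd.DataFrame(rows, columns=["file", "individual", "call_type",
                                "duration_s"]).to_csv(
        audio_dir / "manifest.csv", index=False)
    print(f"wrote {len(clips)} calls "
          f"({len(set(c.individual_id for c in clips))} individuals) "
          f"to {audio_dir}")

    # --- marker kinematics: one sequence per behavior x view -------------
    kin_dir = out / "kinematics"
    kin_dir.mkdir(parents=True, exist_ok=True)
    kin_rows = []
    for behavior in ("breathing", "vocalization"):
        for view in ("dorsal", "lateral"):
            params = synth.kinematic_defaults(
                behavior, view, n_events=200, noise_cm=0.01,
                seed=int(rng.integers(0, 2**31 - 1)))
            res = synth.synth_kinematic_sequence(params)
            stem = f"{behavior}_{view}"
            write_track_csv(kin_dir / f"{stem}_track.csv", res.track)
            res.events.to_csv(kin_dir / f"{stem}_truth.csv", index=False)
            kin_rows.append((behavior, view, params.frame_rate_hz,
                             len(res.events)))
            print(f"  {stem}: {len(res.events)} events, "
                  f"{res.track.n_frames} frames")
    pd.DataFrame(kin_rows, columns=["behavior", "view", "frame_rate_hz",
                                    "n_events"]).to_csv(
        kin_dir / "manifest.csv", index=False)

    # --- soma masks: 73 labeled elliptical regions ------------------------
    soma_dir = out / "somata"
    soma_dir.mkdir(parents=True, exist_ok=True)
    soma = synth.synth_soma_masks(
        synth.SynthSomaParams(seed=int(rng.integers(0, 2**31 - 1))))
    morpho.write_label_png(soma_dir / "labels.png", soma.labels)
    soma.truth.to_csv(soma_dir / "truth.csv", index=False)
    (soma_dir / "scale.txt").write_text(f"{soma.um_per_px}\n")
    print(f"wrote {soma.truth.shape[0]} somata to {soma_dir} "
          f"({soma.um_per_px} um/px)")


if __name__ == "__main__":
    main()
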