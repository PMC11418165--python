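#!/usr/bin/env python
"""Call-type separation in cepstral feature space.

Per call (>= 0.15 s): 15 MFCCs + deltas over 20 segments, mel band
250-5000 Hz, MFCC 0 excluded -> 560-dim vector. PCA to 3 components,
per-type silhouette on the scores.

Writes results/tables/pca_scores.csv, pca_summary.csv and a score
scatter figure.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from geckovox import features as feat
from geckovox.audio import read_wav

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path,
                        default=ROOT / "results" / "data" / "audio")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    manifest = args.data / "manifest.csv"
    if not manifest.is_file():
        raise SystemExit(f"{manifest} missing - run 01_synthesize_dataset.py")
    mf = pd.read_csv(manifest)
    clips = [read_wav(args.data / r.file, r.individual, r.call_type)
             for r in mf.itertuples()]
    kept = [c for c in clips if c.duration_s >= feat.MIN_PCA_DURATION_S]
    print(f"{len(kept)}/{len(clips)} calls kept "
          f"(>= {feat.MIN_PCA_DURATION_S} s)")

    fb = feat.build_mel_filterbank(fs=kept[0].sample_rate_hz)
    X = np.stack([feat.call_features(c, fb=fb).feature_vector for c in kept])
    pca = feat.run_pca(X, n_components=3)
    labels = [c.call_type for c in kept]
    sil = feat.cluster_separation(pca.scores, labels)

    tables = args.out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    scores = pd.DataFrame(pca.scores, columns=["PC1", "PC2", "PC3"])
    scores.insert(0, "call_type", labels)
    scores.insert(0, "individual", [c.individual_id for c in kept])
    scores.insert(0, "call_id", [c.source for c in kept])
    scores.to_csv(tables / "pca_scores.csv", index=False,
                  float_format="%.6g")
    pd.DataFrame(
        {
            "call_type": list(sil),
            "silhouette": [sil[k] for k in sil],
            "explained_var_pc1_3":
                [pca.explained_variance_fraction.sum()] * len(sil),
        }
    ).to_csv(tables / "pca_summary.csv", index=False, float_format="%.6g")

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    colors = {"type1": "tab:blue", "type2": "tab:green", "type3": "tab:red"}
    for (i, j), ax in zip([(0, 1), (0, 2)], axes):
        for ct, col in colors.items():
            m = np.array(labels) == ct
            ax.scatter(pca.scores[m, i], pca.scores[m, j], s=12, c=col,
                       label=ct, alpha=0.7)
        ax.set_xlabel(f"PC{i + 1}")
        ax.set_ylabel(f"PC{j + 1}")
    axes[0].legend()
    fig.tight_layout()
    figdir = args.out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(figdir / "pca_scores.png", dpi=150)

    ev = ", ".join(f"PC{k + 1} {v:.1%}"
                   for k, v in enumerate(pca.explained_variance_fraction))
    print(f"explained variance: {ev}")
    for ct, v in sil.items():
        print(f"  silhouette {ct}: {v:.3f}")
    if sil["type2"] < min(sil["type1"], sil["type3"]):
        print("type 2 (the blend) overlaps both pure types, as built")


if __name__ == "__main__":
    main()
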