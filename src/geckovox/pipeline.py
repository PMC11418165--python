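"""End-to-end orchestration: synthesize -> spectra -> PCA -> kinematics ->
morphometry, with a reproducibility manifest.

A single :class:`PipelineConfig` holds every stage's parameters (defaults
equal the analysis parameters used throughout: 250 Hz/6th-order analysis
high-pass, 4096-point FFTs, 256-point Welch window, 15 MFCCs over 20
segments, 250-5000 Hz mel band, 3 principal components, 5 µm / 100 µm²
histogram bins). One global seed expands into per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, in fixed stage order, so stages
are individually reproducible. The manifest records the config, its hash,
the derived stage seeds and a SHA-256 checksum of every output file:
re-running an identical config reproduces the manifest bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import kinematics as kin
from . import morphometry as morpho
from . import spectral, synth
from .audio import write_wav

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_STAGES = ("synth", "spectral", "features", "kinematics", "morphometry")


class PipelineError(RuntimeError):
    """Raised with the failing stage's name; partial results stay on disk."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class PipelineConfig:
    seed: int = 0
    synthesize: bool = True
    audio_dir: str | None = None        # used when synthesize=False

    # synthetic dataset sizes
    n_per_type: int = 5
    n_individuals: int = 3
    snr_db: float = 25.0
    kin_n_events: int = 30
    kin_noise_cm: float = 0.01
    n_somata: int = 30

    # analysis parameters (defaults = the study's stated values)
    hp_cutoff_hz: float = 250.0
    hp_order: int = 6
    nfft: int = 4096
    welch_window: int = 256
    n_mfcc: int = 15
    n_segments: int = 20
    n_mel_filters: int = 20
    mel_fmin_hz: float = 250.0
    mel_fmax_hz: float = 5000.0
    pca_components: int = 3
    smooth_cutoff_hz: float = 10.0
    smooth_order: int = 4
    min_prominence_cm: float = 0.02
    um_per_px: float = 0.5
    diam_bin_um: float = 5.0
    area_bin_um2: float = 100.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            stage: int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
            for stage, child in zip(_STAGES, children)
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write a manifest; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "stages": {},
        "outputs": {},
    }
    manifest_path = outdir / "manifest.json"

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"][stage] = "ok"
        for p in outputs:
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)

    def fail(stage: str, message: str) -> None:
        manifest["stages"][stage] = f"failed: {message}"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise PipelineError(stage, message)

    # ---- synth / ingestion -------------------------------------------------
    if config.synthesize:
        clips = synth.synth_call_dataset(
            config.n_per_type, config.n_individuals,
            seed=seeds["synth"], snr_db=config.snr_db,
        )
        audio_dir = outdir / "audio"
        audio_dir.mkdir(exist_ok=True)
        wavs = []
        for clip in clips:
            p = audio_dir / f"{clip.source}.wav"
            write_wav(p, clip)
            wavs.append(p)
        manifest_rows = pd.DataFrame(
            {
                "file": [p.name for p in wavs],
                "individual": [c.individual_id for c in clips],
                "call_type": [c.call_type for c in clips],
            }
        )
        manifest_csv = audio_dir / "manifest.csv"
        manifest_rows.to_csv(manifest_csv, index=False)
        record("synth", wavs + [manifest_csv])
    else:
        if not config.audio_dir or not Path(config.audio_dir).is_dir():
            fail("preprocess", "audio directory missing and synthesis disabled "
                 "(set synthesize=true or provide audio_dir)")
        from .audio import read_wav

        mf = pd.read_csv(Path(config.audio_dir) / "manifest.csv")
        clips = [
            read_wav(Path(config.audio_dir) / row.file,
                     individual_id=row.individual, call_type=row.call_type)
            for row in mf.itertuples()
        ]
        manifest["stages"]["synth"] = "skipped (external audio)"

    # ---- spectral ----------------------------------------------------------
    try:
        psds = [
            spectral.call_psd(c, config.hp_cutoff_hz, config.hp_order,
                              nfft=config.nfft, window_len=config.welch_window)
            for c in clips
        ]
        inds = [c.individual_id for c in clips]
        types = [c.call_type for c in clips]
        averages = spectral.average_spectra(psds, inds, types)
        rows = []
        for ct, avg in averages.items():
            rows.append(
                {
                    "call_type": ct,
                    "n_calls": avg.n_calls,
                    "n_individuals": avg.n_individuals,
                    "peak_hz": spectral.peak_frequency(avg.mean),
                    "band_fraction_500_5000":
                        spectral.band_power_fraction(avg.mean),
                }
            )
        spec_csv = outdir / "spectra_summary.csv"
        pd.DataFrame(rows).to_csv(spec_csv, index=False, float_format="%.6g")
        mean_csv = outdir / "grand_mean_psd.csv"
        pd.DataFrame(
            {"freq_hz": psds[0].freqs_hz}
            | {f"psd_{ct}": avg.mean.psd for ct, avg in averages.items()}
        ).to_csv(mean_csv, index=False, float_format="%.8g")
        record("spectral", [spec_csv, mean_csv])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("spectral", str(exc))

    # ---- features / PCA ----------------------------------------------------
    try:
        fb = feat.build_mel_filterbank(
            config.n_mel_filters, config.mel_fmin_hz, config.mel_fmax_hz,
            nfft=config.nfft, fs=clips[0].sample_rate_hz,
        )
        pca_clips = [c for c in clips
                     if c.duration_s >= feat.MIN_PCA_DURATION_S]
        pca_types = [c.call_type for c in pca_clips]
        vectors = np.stack([
            feat.call_features(c, fb=fb, n_coeffs=config.n_mfcc,
                               n_segments=config.n_segments).feature_vector
            for c in pca_clips
        ])
        pca = feat.run_pca(vectors, n_components=config.pca_components)
        sil = feat.cluster_separation(pca.scores, pca_types)
        scores_csv = outdir / "pca_scores.csv"
        pd.DataFrame(
            {
                "call_id": [c.source for c in pca_clips],
                "individual": [c.individual_id for c in pca_clips],
                "call_type": pca_types,
            }
            | {f"PC{j + 1}": pca.scores[:, j]
               for j in range(pca.scores.shape[1])}
        ).to_csv(scores_csv, index=False, float_format="%.6g")
        pca_json = outdir / "pca_summary.json"
        pca_json.write_text(json.dumps(
            {
                "explained_variance_fraction":
                    [round(float(v), 8) for v in
                     pca.explained_variance_fraction],
                "silhouette_per_type":
                    {k: round(v, 8) for k, v in sil.items()},
            },
            indent=2, sort_keys=True,
        ))
        record("features", [scores_csv, pca_json])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("features", str(exc))

    # ---- kinematics --------------------------------------------------------
    try:
        rng = np.random.default_rng(seeds["kinematics"])
        all_events: list[kin.MovementEvent] = []
        for behavior in ("breathing", "vocalization"):
            for view in ("dorsal", "lateral"):
                params = synth.kinematic_defaults(
                    behavior, view,
                    n_events=config.kin_n_events,
                    noise_cm=config.kin_noise_cm,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                res = synth.synth_kinematic_sequence(params)
                smoothed = kin.smooth_track(res.track, config.smooth_cutoff_hz,
                                            config.smooth_order)
                series = kin.compute_series(smoothed)
                all_events += kin.extract_events(
                    series, behavior, config.min_prominence_cm)
        events_csv = outdir / "kinematic_events.csv"
        kin.events_to_frame(all_events).to_csv(events_csv, index=False,
                                               float_format="%.6g")
        stats_out = {}
        for axis in ("antero_posterior", "dorso_ventral"):
            ev = [e for e in all_events if e.axis == axis]
            for response in ("displacement", "duration"):
                c = kin.compare_behaviors(ev, response)
                stats_out[f"{axis}_{response}"] = {
                    "F": round(c.F, 6),
                    "df": list(c.df),
                    "p": round(c.p, 8),
                    "means": {k: round(v, 6) for k, v in c.group_means.items()},
                    "sds": {k: round(v, 6) for k, v in c.group_sds.items()},
                }
        stats_json = outdir / "kinematics_stats.json"
        stats_json.write_text(json.dumps(stats_out, indent=2, sort_keys=True))
        record("kinematics", [events_csv, stats_json])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("kinematics", str(exc))

    # ---- morphometry -------------------------------------------------------
    try:
        soma = synth.synth_soma_masks(
            synth.SynthSomaParams(
                n_somata=config.n_somata,
                um_per_px=config.um_per_px,
                seed=seeds["morphometry"],
            )
        )
        meas = morpho.measure_soma(soma.labels, soma.um_per_px)
        meas_csv = outdir / "soma_measurements.csv"
        morpho.measurements_to_frame(meas).to_csv(meas_csv, index=False,
                                                  float_format="%.6g")
        summary = {
            m: dataclasses.asdict(s)
            for m, s in morpho.summarize_all(meas).items()
        }
        summary_json = outdir / "soma_summary.json"
        summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True,
                                           default=float))
        record("morphometry", [meas_csv, summary_json])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("morphometry", str(exc))

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
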