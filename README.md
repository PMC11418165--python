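# geckovox

Acoustic, kinematic and neuroanatomical analysis of tokay gecko
(*Gekko gecko*) alarm calls: a tested re-implementation of a complete
study workflow, driven by a seeded synthetic-data generator.

Hand-held tokay geckos produce three visually distinguishable alarm-call
types — a sinusoidal call (type 1), a train of irregularly spaced pulses
(type 3), and an intermediate form mixing both (type 2). This package
implements the three analysis streams such a study needs, for
bioacousticians and comparative physiologists who want the pipeline
without the original (undeposited) recordings:

1. **Spectral analysis** — per-call Welch power spectral density
   (4096-point FFT, 256-point Hann window) after a 250 Hz 6th-order
   Butterworth high-pass; spectrograms with exactly 100 time bins per
   call (window = N/100 samples, Hamming, zero-padded to 4096 points →
   10.8 Hz resolution at 44.1 kHz); two-stage per-type averaging (mean
   per individual, then across individuals); peak frequency and
   band-power fraction P(500–5000 Hz)/P(≥250 Hz).
2. **Call-type separation** — 15 mel-frequency cepstral coefficients
   (MFCCs) and delta coefficients over 20 non-overlapping segments per
   call, mel band edges 250–5000 Hz (the species' hearing range),
   mel(f) = 2595·log₁₀(1 + f/700); MFCC 0 excluded → a 20·(14+14) =
   560-dimensional vector per call; PCA (centered, unscaled) to three
   components and per-type silhouette.
3. **Laryngeal kinematics** — gape (anterior jaw-marker distance),
   antero-posterior (dorsal view) and dorso-ventral (lateral view)
   larynx–jaw distances from five tracked markers; zero-phase Butterworth
   smoothing; per-event total movement and cycle duration; one-way linear
   model on log₁₀ responses contrasting breathing vs vocalization; R² of
   larynx-on-gape regression as a coordination index.
4. **Motoneuron morphometry** — minimum/maximum Feret (caliper) diameters
   and areas of labeled soma regions, with min/max/mean/s.e.m. summaries
   and fixed-width histograms (5 µm diameters, 100 µm² areas).

A synthetic-data generator (`geckovox.synth`) emulates all three data
streams with known ground truth — call populations with ~1 kHz peak
frequency and ≥85 % of power in 500–5000 Hz; movement-event populations
matching the study's breathing/vocalization displacement and duration
statistics (e.g. vocalization antero-posterior displacement
0.54 ± 0.40 cm, breathing cycle duration 1.28 ± 0.38 s); 73 elliptical
somata calibrated to the reported 18.1 µm mean minimum diameter — so
every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write tables and figures under `results/`:

```sh
python analysis/01_synthesize_dataset.py --seed 1
python analysis/02_call_spectra.py
python analysis/03_call_types_pca.py
python analysis/04_larynx_kinematics.py
python analysis/05_motoneuron_morphometry.py
```

Step 02 prints, for the 360-call population (20 calls/type × 6
individuals):

```
median band-power fraction (0.5-5 kHz / >=250 Hz): 0.996
  type1: grand-mean peak 1001 Hz over 6 individuals / 120 calls
```

i.e. virtually all analyzed power sits in the 0.5–5 kHz band and every
call type's grand-mean spectrum peaks within one frequency bin of the
1 kHz carrier. Step 03 reports the cluster structure of the call types
in principal-component space:

```
explained variance: PC1 21.0%, PC2 9.2%, PC3 5.2%
  silhouette type1: 0.179
  silhouette type2: 0.125
  silhouette type3: 0.473
```

— the two pure types form separate clusters while the blended type 2 has
the lowest silhouette, overlapping both. Step 04 contrasts behaviors:

```
antero_posterior displacement: F(1,396) = 1035.1, p = 1.6e-112;
  vocalization 0.53 +/- 0.34 cm vs breathing 0.06 +/- 0.03 cm
```

so the extracted events recover the configured populations: larynx
movements are larger and faster during vocalization than breathing.
Step 05 measures the 73 synthetic somata:

```
min_diam_um: mean 18.4 um (s.e.m. 1.0; range 1.3-41.0; n=73;
  generator truth mean 18.5)
```

A `geckovox` CLI exposes the same stages
(`geckovox synth|segment|spectra|pca|kinematics|morpho|run`), and
`geckovox run --seed N --out DIR` executes the full pipeline with a
checksummed reproducibility manifest.

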