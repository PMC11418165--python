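# Methods

This note documents the models, parameter choices and numerical
conventions behind `geckovox`, and what the synthetic-data tests do and
do not establish about real recordings.

## Synthetic alarm calls

Three waveform models emulate the three alarm-call types:

* **Type 1 (sinusoidal).** A harmonic stack of 4 partials on a 1 kHz
  carrier with 6 dB-per-harmonic roll-off, amplitude-modulated by a
  raised-cosine envelope at 25 Hz (90 % depth), with random partial
  phases per call.
* **Type 3 (pulse train).** Exponentially decaying tone pulses (decay
  τ = 12 ms) on the same carrier, at gamma-distributed inter-pulse
  intervals with mean rate 20 s⁻¹ and coefficient of variation 0.4.
  The gamma model is the simplest positive-support jitter model; with
  cv = 0 the pulses are regular and the first pulse sits half an
  interval in, so an n-pulse train has exactly n interior envelope
  maxima. Pulse partials roll off at 3 dB per harmonic — impulsive
  excitation is spectrally flatter than sustained phonation.
* **Type 2 (intermediate).** A blend of the two components, equalized
  to matched RMS before mixing (peak-matched mixing would let the tonal
  component dominate the energy), with a per-call mix fraction drawn
  from U(0.15, 0.85) so the type genuinely spans the continuum between
  the pure types rather than forming a third compact cluster.

Every call is peak-normalized, given 10 ms raised-cosine edge fades,
degraded with broadband Gaussian noise at 25 dB SNR, and re-normalized.
Per-call durations are uniform on 0.1–0.6 s (no durations are otherwise
constrained; 0.1 s keeps the 20-segment MFCC windows at ≥ 220 samples).
Datasets impose per-individual parameter jitter (carrier s.d. 10 Hz
between individuals, 5 Hz between calls; modulation and pulse rates
log-normal with σ = 0.1), which leaves the population grand-mean
spectral peak within a frequency bin of 1 kHz.

With these defaults the population reproduces the two printed spectral
facts the generator is calibrated to: ≥ 85 % of analyzed power (above
the 250 Hz high-pass) between 500 Hz and 5 kHz, and a grand-mean peak
near 1 kHz for every type. The synthetic calls are *cleaner* than field
recordings — no reverberation, no overlapping calls, no microphone or
handling noise — so segmentation and classification results here are
upper bounds on real-data performance.

## Spectral analysis conventions

* Spectrogram: window length = ⌊N/100⌋ samples (exactly 100 time bins
  regardless of call length), Hamming taper, non-overlapping windows
  zero-padded to 4096 FFT points. Non-overlap is forced by the stated
  bin count; resolution is fs/4096 = 10.8 Hz at 44.1 kHz.
* Welch PSD: 256-point Hann window, 50 % overlap (the estimator's
  conventional default), 4096-point zero-padded FFT, one-sided density
  normalization. Only ratios and argmaxes of the PSD are interpreted,
  so the absolute scaling convention is immaterial but fixed.
* The per-call analysis spectrum applies the 250 Hz 6th-order
  Butterworth high-pass (zero-phase, forward–backward) before Welch.
* Band-power fractions integrate the PSD trapezoidally; the denominator
  starts at the 250 Hz analysis cutoff because the filtered signal
  carries no interpretable power below it (configurable).
* Two-stage averaging (mean per individual, then unweighted mean over
  individuals) keeps prolific individuals from dominating the type
  grand mean; the reported dispersion is ±1 s.d. over individual means.
* Peak frequency ties break toward the lower frequency (first argmax).

## Cepstral features and PCA

The mel filterbank uses the HTK closed form
mel(f) = 2595·log₁₀(1 + f/700) with 20 triangular filters whose centers
are equally spaced in mel between 250 and 5000 Hz; every filter's
support lies inside the band. Twenty filters exceed the retained
cepstral order (15) while keeping the filters wider than the 10.8 Hz
FFT bins. Per segment (⌊N/20⌋ samples, Hamming-windowed,
magnitude-squared spectrum): filterbank energies → log (floored at
1e-12 for silent segments) → orthonormal DCT-II → 15 coefficients.
No pre-emphasis and no liftering (both disabled; the analysis uses the
coefficients only as PCA inputs, where monotone per-coefficient
rescalings are immaterial to centering). Deltas use the standard ±2
regression formula with edge replication. MFCC 0 and its deltas are
excluded (they encode overall energy only), making the 560-dimensional
feature vector exactly invariant to call amplitude.

PCA centers but does not variance-scale (all features are already on
the cepstral scale); components come from a full SVD with the sign of
each component fixed so its largest-magnitude loading is positive.
Cluster separation is the mean silhouette per call type on the first
three scores (Euclidean); a single-member type is reported as NaN.

Calls shorter than 0.15 s are excluded from the PCA
(`features.MIN_PCA_DURATION_S`): with 20 segments they give < 8 ms
windows whose spectral smearing (main-lobe width > 250 Hz) dominates
the cepstra and masks type structure. The study design this package
follows likewise analyzed only calls long enough for its segment
windows. The variance explained by the leading components depends on
the recording population and is reported, not asserted.

## Synthetic kinematics and event extraction

Five markers (anterior/posterior upper and lower jaw, larynx) are
simulated at 200 frames s⁻¹ in each view. Each movement event displaces
the larynx marker along the line away from the view's reference jaw
marker by a half-sine excursion returning to baseline — a smooth,
single-cycle shape consistent with one breath or one vocalization.
Event peak amplitudes and durations are drawn from **gamma**
distributions with exactly the configured mean and s.d. per
behavior × view cell (vocalization: antero-posterior 0.54 ± 0.40 cm /
0.89 ± 0.31 s, dorso-ventral 0.80 ± 0.71 cm / 0.70 ± 0.36 s; breathing:
0.06 ± 0.03 cm / 1.28 ± 0.38 s, 0.26 ± 0.14 cm / 0.93 ± 0.18 s). A
zero-truncated normal was rejected: truncating N(0.54, 0.40²) at zero
shifts the population mean by ≈ +0.07 cm, so the generated population
would no longer have the statistics it is calibrated to; the gamma has
positive support, the exact first two moments, and a physically
plausible right skew. Inter-event gaps are uniform on 0.6–1.0 s and
marker jitter is Gaussian (default s.d. 0.01 cm ≈ realistic tracking
noise). Jaw coordination is deliberately loose: each event's gape
excursion (on the anterior upper-jaw marker) gets an independent random
gain (uniform, mean 0.3 of the larynx amplitude) and onset offset
(±30 % of the event duration), giving larynx-on-gape R² values in the
0.1–0.6 range rather than a hard-wired unity coupling.

Tracks are smoothed with a zero-phase 4th-order Butterworth low-pass at
10 Hz — events last 0.6–1.3 s, so their content sits far below the
cutoff while frame-to-frame tracking jitter is removed. Event
extraction then proceeds in three steps:

1. candidate peaks of the larynx distance signal with prominence
   ≥ 0.02 cm (scipy `find_peaks`);
2. event windows from flank crossings: the resting baseline is the
   20th percentile of the whole signal; each flank is walked down to a
   small threshold above baseline (5 % of the excursion, floored at
   0.3 × the prominence threshold) and the two crossing times at h and
   2h are linearly extrapolated to the baseline itself, removing the
   threshold-height bias in the cycle duration. Overlapping windows
   merge; candidate bumps rising less than the prominence threshold
   above baseline are discarded as baseline noise.
3. total movement = the event's peak height above baseline, with the
   peak taken from a local quadratic fit (window ±12 % of the event
   width) and the baseline from the median of the signal **outside**
   all event windows (unbiased under symmetric noise, unlike a low
   percentile). For a single excursion returning to baseline this
   equals the max − min of the underlying movement, and it is exact in
   the noiseless case; on noisy data it avoids the systematic
   inflation a raw max − min suffers when the excursion is comparable
   to the residual noise (the breathing antero-posterior cell, mean
   0.06 cm, is the demanding case).

Events smaller than the prominence threshold are undetectable by
construction; at the breathing antero-posterior defaults this censors
≈ 4 % of events and biases the recovered mean up by ≈ 0.002 cm — within
one standard error at n = 200 and inherent to any thresholded detector.

The behavior contrast is a one-way fixed-effect linear model (= one-way
ANOVA) on log₁₀ responses with behavior as the only factor, F on
(1, n−2) df, run separately per axis; no individual term is included
(matching a two-animal pooled design), which is a documented limitation
rather than a recommendation. Group means and s.d. are reported on the
original scale. Jaw–larynx coordination is the squared Pearson
correlation (identically the OLS R²) between the gape and larynx
distance profiles over a whole sequence; a zero-variance gape yields
NaN.

## Synthetic somata and morphometry

Somata are filled rotated ellipses on a 16-bit label raster
(0.5 µm/pixel, 1280² px default). Minor diameters are gamma-distributed
with mean 18.1 µm and s.d. 9.4 µm (s.e.m. 1.1 µm × √73); the axis ratio
is 1 + gamma(mean 0.85, s.d. 0.35), giving a mean major axis near
33.5 µm; orientations are uniform. Placement is by rejection sampling
on bounding circles with bounded retries (capacity error otherwise).
The ground-truth table stores each ellipse's analytic axes and area
π·a·b/4.

Measurement treats each pixel as a unit square: the convex hull is
taken over pixel corners, so a w-pixel-wide region measures exactly w
pixels across. Max Feret diameter is the largest pairwise hull-vertex
distance; min Feret is the smallest projection width over caliper
rotations in 1° steps; area is the pixel count × (µm/px)². A
single-pixel region is degenerate and flagged, with both diameters
reported as one pixel pitch. Rasterization plus the corner convention
bias diameters by roughly +0.5–1 px (≈ +0.3–0.5 µm at 0.5 µm/px),
well inside the sampling error of a 73-cell population. Histograms use
left-closed, right-open bins anchored at zero; the diameter bin
defaults to 5 µm (the published-figure convention; 4 µm is available)
and the area bin to 100 µm².

## Pipeline reproducibility

One global seed expands to per-stage seeds via
`numpy.random.SeedSequence(seed).spawn` in fixed stage order, so stages
rerun in isolation reproduce their outputs. The manifest records the
config, its SHA-256 hash, the derived stage seeds and a checksum of
every output file; identical configs reproduce the manifest
bit-for-bit. PCA score signs are fixed by the largest-loading
convention, so they too are deterministic.

## Problem sizes

Defaults used by the analysis scripts and acceptance checks: 360 calls
(20 per type × 6 individuals), 200 movement events per behavior × view
cell, 73 somata — the same population sizes the generator's calibration
statistics refer to. The test suite uses smaller populations where only
contracts (shapes, invariances, error cases) are exercised.

## Known limitations

* The synthetic calls lack reverberation, amplitude overloading and
  non-stationary background noise; segmentation thresholds tuned here
  may need adjustment on field recordings.
* The event extractor assumes single-excursion events on a stationary
  baseline; drifting baselines (posture changes) would require a
  rolling baseline estimate.
* Min-Feret at 1° caliper steps under-resolves very elongated regions
  by at most (1 − cos 0.5°) ≈ 4 × 10⁻⁵ relative — negligible here.
* The morphometry operates on given 2-D label masks; segmentation of
  fluorescence images is out of scope.
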