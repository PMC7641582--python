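# Methods

This note documents the models, numerical choices, and limitations of the
`stmtrf` pipeline.  Nothing here states an empirical result that the test
suite or the analysis drivers do not themselves compute.

## Stimulus synthesis

Words are parametric, not recordings: a harmonic source (f0 drawn in
100–140 Hz with a 15% declination and 1% jitter at 4–7 Hz) is shaped by
three linear formant trajectories (F1 300–800, F2 900–2400, F3 2300–3400 Hz,
Gaussian resonance gains with 90/130/180 Hz bandwidths), given a −6
dB/octave source tilt (the natural voicing slope; a shallower tilt makes
the modulation grid peak above 0.5 cycles/octave), an optional 30–60 ms
band-limited onset burst, and a single-syllable amplitude envelope.
Durations are drawn from the stated distribution (mean 591, SD 78, clipped
to 372–903 ms).  Default rate is 16 kHz — every bandwidth precondition in
the pipeline (vocoder hi = 5 kHz, auditory spectrogram up to 7040 Hz) is
satisfied at a third of the 44.1 kHz compute; the code accepts any rate
≥ the stated minima.  All synthesis is deterministic given (word id, seed).

What the generator does **not** emulate: co-articulation, consonant
clusters, speaker variability, f0 accents, or recording-channel effects.
A green test therefore establishes that the *pipeline* behaves correctly on
speech-like spectrotemporal content, not that it reproduces results on real
recordings.

## Vocoder

Channel edges are equally spaced on the Greenwood position axis
(A = 165.4, a = 2.1, k = 0.88) between 70 and 5000 Hz; centers default to
the midpoint-position convention and are overridable (`centers_override`),
since the published 24 center frequencies differ from any simple convention
by ≲ 2%.  Analysis and synthesis band-passes are 4th-order Butterworth
applied forward–backward (zero phase, so envelope timing stays aligned with
the 80 Hz features); envelopes are half-wave rectified and smoothed by a
zero-phase 2nd-order 30 Hz low-pass.  Carrier noise is drawn once per
channel per word from the seed.

Two physical effects bound envelope fidelity below naive expectations:
narrowband noise carriers have intrinsic envelope fluctuations at roughly
their bandwidth, and contiguous 4th-order bands leak at the shared edges.
Channel-envelope conservation and across-seed envelope similarity are
therefore asserted on energetic channels away from filter transients at
measured levels (mean r > 0.85), not at unity.

## Feature spaces

All spaces are delivered at 80 Hz via polyphase resampling.  The envelope
space is *exactly* the column sum of the spectrogram space (24 Greenwood
channel envelopes), so the two are consistent by construction.  The
spectral derivative is the half-wave-rectified first difference.

The auditory spectrogram is an analytic Gaussian constant-Q filterbank
(128 channels, log-spaced 180–7040 Hz, bandwidth = center/24 matching the
~24 channels/octave spacing) applied in the Fourier domain of the whole
waveform, with 8 ms frame averaging and first-order leaky integration
(8 ms time constant), no compression.  An STFT front end was tried first
and rejected: its fixed time-frequency tiling cannot resolve 2–8
cycles/octave spectral modulations at low center frequencies.

The modulation decomposition multiplies the 2-D FFT of the (time ×
log-frequency) spectrogram with separable band-pass responses
H(f) = (f/Ω)²·exp(2(1−f/Ω)) (peak at Ω, zero at DC, ~octave bandwidth,
order-2 rolloff) at 5 scales × 5 rates, split into up/down quadrants for
the two sweep directions; magnitudes are averaged over the 128 channels and
both directions (the 6400-dimensional per-frame tensor is exposed for
inspection).  Grid ordering is fixed everywhere: rows = spectral scale,
columns = temporal rate.

Phonetic features use a shipped ARPABET-style CSV table mapping each
phoneme to 13 binary features; postalveolars fold into Alveolar, glides
into Liquid, labiodental/dental are merged, and composites (diphthongs,
affricates) carry the mean of their component vectors over their whole
span.

`prepare` z-scores acoustic columns per trial (constant columns are zeroed
and flagged), leaves phonetic indicators untouched, and zero-pads each
trial by the extreme lags (8 samples before onset, 24 after offset at the
default −100..300 ms range).

## Models

Ridge is solved in closed form (primal or dual by shape; the two agree
exactly for λ > 0, and λ = 0 falls back to minimum-norm least squares).
Banded ridge rescales each column band by 1/√λ_b and solves unit-penalty
ridge, so equal λs reduce to plain ridge identically.  Within each trial,
predictors and targets are mean-centred before solving, which implements an
unpenalized intercept; the bare solver matches the normal-equations form so
it can be verified against a brute-force oracle.

Cross-validation fits one model per trial and, for each held-out trial,
predicts from the *average* of the other trials' weights, restricted to the
0..250 ms lag blocks; accuracy is the Pearson correlation per output over
the full padded epoch.  The λ grid is 17 log₂-equispaced values with
exponents 0..20 (the printed grid in the source material is internally
inconsistent; this choice preserves count, range, and spacing).  λ
selection takes the per-(participant, condition) argmax and returns the
mode, ties toward smaller λ; a pooled-peak alternative is provided.
Decoding negates the lag shifts (positive lag = neural sample after the
decoded stimulus sample) and runs on the leading 50 principal components
fitted on all trials jointly.  Single-lag decoding fits one one-lag model
per 12.5 ms step over −50..250 ms with per-lag λ optimization.

**Known limitation (estimator bias in decoding).**  A decoding trial has
~100 samples against 20 sensors × 33 lags = 660 predictors, so every
per-trial fit is underdetermined; averaging the per-trial solutions gives a
biased decoder whose held-out accuracy plateaus near r ≈ 0.90–0.95 even on
noiseless data (and mapping 25 modulation cells through 20 sensors is not
an injective inverse problem).  This is a property of the
fit-per-trial-then-average procedure at word-length trials, not of the
solver; encoding fits (few features, many samples per trial) recover ground
truth essentially exactly.

## Inference

The 2 × 3 repeated-measures ANOVA is computed from orthonormal contrasts
(balanced complete designs only): for an effect with q contrasts,
F = (n·‖mean score‖²/q)/(residual SS/q(n−1)), partial η² =
SS_eff/(SS_eff+SS_err), and Greenhouse-Geisser ε from the contrast-score
covariance, applied to every 3-level effect.  The implementation matches
`pingouin` to numerical precision (a test asserts this) but runs ~50×
faster, which the 1000-simulation type-I calibration check needs.  Simple
effects of detail are reported per prior level.

Permutation nulls re-run the full fixed-λ CV pipeline per permutation.
Within-trial shuffling jointly permutes all (cell, time) entries of a
trial's features; across-trial shuffling permutes the word→trial assignment
within each condition cell, excluding the identity whenever a cell has ≥ 2
trials.  z-scores subtract the null mean and divide by the null SD per
condition (and participant).  FDR is Benjamini–Hochberg at q = 0.05,
treating the 25 grid cells (or the lags) as a flat family.

## Simulation world

Sensor data are generated by the forward encoding model: condition gain ×
(lagged features · ground-truth TRF) + white Gaussian noise.  The
ground-truth TRFs are biphasic (positive bump at 87.5 ms, negative at
150 ms, 30 ms width) with random feature/sensor loadings.  The crossover
gains are Mismatch 0.5/1.0/1.5 and Match 1.5/1.0/0.5 over 3/6/12 channels —
a stand-in for prediction-error coding, not a mechanistic claim.  Noise SD
is calibrated to a target SNR against the measured noiseless response power
(0 dB by default).  "Participants" are independent noise draws over a fixed
stimulus set and generating model, mirroring a fixed experimental stimulus
list; sensors split into hemispheres by array half (the stand-in for a
planar layout coordinate).  Noise is white across sensors and time;
correlated-noise models are out of scope.

## Schematic model

Binary glyph renderings of "clay" and "fast" (7 × 5 letter bitmaps,
pixel-doubled so stroke width is comparable to the degradation kernels, as
for rendered text) are degraded by local mean filters (8-pixel = 3 × 3
minus center; 4-pixel = 2 × 2; circular boundary so the filters conserve
total mass exactly), mixed with uniform noise of SD 0.5 (support ±0.5·√3)
and normalized to sum 1 (non-positive sums are redrawn); predictions get
the same noise-and-normalize treatment.  Sharpened = input × prediction,
renormalized; prediction error = input − prediction, unnormalized.
Fidelity is the squared Pearson correlation with the clean spoken-word
pattern; |PE| is the absolute sum.  At the default resolution the
prediction-error scheme shows the full published pattern, including higher
fidelity for matching priors at low detail (the "negative prediction
error" regime) and the crossover at high detail.

## DSS

The total covariance sums unnormalized per-trial covariances; the biased
covariance comes from the trial average.  Whitening drops eigenvalues below
1e-10 of the maximum (warning on rank deficiency).  Scores are the
whitened-evoked eigenvalues: 1/N for perfectly repeatable trials, ~1/N² for
independent noise.  DSS is applied to per-trial TRF weight matrices (lags
as the time axis), keeping 3 components by default before back-projection
and left-hemisphere sensor-RMS summarization.

## Numerical conventions

Lag-matrix columns are feature-major, lag-minor; out-of-range samples are
zero.  Lags must be integer multiples of the 12.5 ms sample period.
Zero-variance prediction or target series yield r = 0 rather than NaN.
Trials shorter than the lag window are excluded with a warning.  All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; word-level streams are keyed by CRC32 of the
word id so that word sets are stable under design changes.
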