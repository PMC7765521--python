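# Methods

## Problem and model

Given a one-hour multichannel interictal iEEG recording in which each channel
carries a binary clinical label (SOZ / non-SOZ), the task is to rank channels
by their probability of belonging to the seizure onset zone. The working
assumption is that epileptogenic cortex produces elevated high-frequency
activity (ripples, 80–250 Hz; fast ripples, 250–600 Hz) even between
seizures, and that this asymmetry is measurable in simple statistics of
bandpassed 20 s windows. Classification operates at the segment level — every
20 s window inherits its channel's label — and channel decisions come from
averaging segment probabilities, which integrates out segment-level noise.

Because segments inherit channel labels, a segment from an SOZ channel that
happens to contain no high-frequency event is still labelled positive; the
segment-level Bayes error is therefore substantial by construction, and the
interesting quantity is the channel-level ranking (AUC), not segment accuracy.

## Pipeline stages and the parameters that matter

**Segmentation** (`segment_seconds = 20`). Non-overlapping, chronologically
ordered windows; a trailing partial window is discarded so every feature sees
a full-length window. The chronological split (defaults 30/5/5/20 minutes =
90 train / 15 validation / 15 discarded / 60 test segments per channel)
follows time-series forecasting practice: test data strictly follows
everything the model saw, with an explicit unused gap between validation and
test. The gap is a configurable field rather than a hard-coded constant.

**Filter bank** (`band_width = 50 Hz`, `filter_order = 3`). Contiguous
equal-width Butterworth bandpass filters covering 100–600 Hz at 2 kHz
sampling (10 bands) or 100–450 Hz at 1 kHz (7 bands), realized as cascaded
second-order sections for numerical stability of narrow high-frequency bands.
Filtering is causal single-pass by default: all downstream features are
phase-insensitive magnitude statistics, so group delay is immaterial; a
zero-phase (forward–backward) flag exists for users who want symmetric
transients. Startup transients are accepted rather than trimmed — at 20 s
(≥ 20 000 samples) per window they are negligible; the stability tests verify
each band's impulse response decays below 1e-6 of its peak well inside a
window. Each segment is filtered with zero initial state (windows are
independent). The upper band edge must stay below 0.95× Nyquist; violations
raise a configuration error instead of silently truncating the bank.

**Features** (fixed order `CV, FI, Var, RMS, DASD, MAV, MMAV, MMAV2, LD, PE,
ShE, RE`; the column order is a public contract). Definitions and numerical
choices:

* CV uses the population standard deviation (divisor L) while Var uses the
  sample variance (divisor L−1). The inconsistency is deliberate: each
  follows its conventional printed definition, and since every feature is
  only compared with itself across segments, a constant divisor convention
  per feature is all that correctness requires.
* MMAV/MMAV2 window indices are 1-based with real-valued thresholds
  0.25·L/0.75·L (no rounding). MMAV2's upper ramp weight `4(i−L)/L` is kept
  in its printed (non-positive) form; `mmav2_abs_weights` switches to the
  conventional `4(L−i)/L`. Either way the feature is a fixed deterministic
  functional, equally usable by the classifier.
* LD applies a floor `ld_epsilon = 1e-12` inside the logarithm because
  bandpassed iEEG always contains non-positive samples.
* PE uses embedding dimension m = 3 and lag τ = 1 (defaults), base-2
  logarithm, and breaks ties by temporal order (stable sort), so constant
  input yields a single pattern and PE = 0. Zero-frequency patterns
  contribute nothing to the sum.
* Spectral entropies use the magnitude-squared one-sided DFT of the
  unwindowed segment, DC bin included, natural logarithm. The Rényi entropy
  is the standard order-γ form (γ = 2 by default),
  `RE = ln(Σ p_f^γ) / (1−γ)`; at γ = 2 it is bounded above by the Shannon
  entropy, which the property tests assert.
* Degenerate inputs (zero mean for CV, zero total power for the spectral
  entropies) map to 0 with a logged warning instead of raising, keeping batch
  extraction total.

The scalar functions are the reference implementation; the pipeline uses a
fused numba kernel over (segments × samples) blocks that matches the scalar
path to ~1e-9 relative (the only differences are floating-point summation
orders). A literal loop-based oracle suite pins both to the defining
equations at 1e-10 relative tolerance.

**Selection** (`mi_bins = 10`). Mutual information between each (subband,
feature) column and the segment label is estimated by equal-width binning
over the observed training range (10 bins, natural log, clipped at zero).
Ten equal-width bins is the common default for binned MI on a few thousand
samples; it is config-exposed, and rankings — the only thing consumed
downstream — are insensitive to moderate changes in the bin count. Subbands
are ranked by mean MI over features, features by mean MI over subbands, both
descending with stable ties (original index order). The grid search evaluates
every (j, k) cell by training the segment classifier on the top-j × top-k
columns (flattened subband-major) and scoring F1 on the validation partition;
ADASYN re-balancing is re-run inside every cell on that cell's feature subset.
Ties in the F1 grid prefer the smallest K, then the smallest J (parsimony).
Classifier hyperparameters stay fixed during the search so the grid varies
only along the two counts. A failing cell scores 0 and is logged rather than
aborting the search.

**Balancing** (`adasyn_k = 5`, `adasyn_beta = 1`). ADASYN with the reference
defaults: the number of synthetics is `G = β(J_in − I_in)`; per-minority-row
allocation is proportional to the majority fraction among its k nearest
neighbors, with largest-remainder rounding so the balance identity
`I_in + Ĩ_in = J_in` holds exactly at β = 1. Synthetic rows interpolate
between a minority row and one of its minority neighbors with u ~ U[0,1].
When no minority row has any majority neighbor the allocation degrades to
uniform (standard edge-case fix). Neighbor distances are computed on
standardized copies by default since subband features differ in scale by
orders of magnitude; within the pipeline the rows are standardized upstream
anyway (see below).

**Classifiers.** LightGBM is the default segment scorer (200 trees, 31
leaves, learning rate 0.1, `max_bin = 63`, deterministic single-threaded
training); the alternative is an RBF-kernel SVM (C = 1, γ = "scale") whose
decision values are Platt-calibrated (paired sigmoid, 3-fold) to
probabilities. None of these hyperparameters are sacred — they are
conventional defaults, all config-exposed and logged per run. Feature
standardization is fit on the original (pre-ADASYN) training rows and reused
for validation and test, so synthetic rows never shift the scale and test
statistics never leak into training. Hard segment decisions use the 0.5
probability threshold.

**Evaluation.** Segment metrics follow
`Sen = 100·TP/(TP+FN)`, `Spe = 100·TN/(TN+FP)`, `F1 = TP/(TP+0.5(FP+FN))`
with focal (SOZ-channel) segments positive; a metric whose denominator is
empty is reported as missing rather than 0. The channel score is the
arithmetic mean of the channel's test-segment probabilities. Channel AUC
sweeps thresholds over the distinct channel scores and integrates sensitivity
over false-positive rate with the trapezoid rule; tied scores produce
diagonal ROC segments, making the sweep exactly equal to the Mann–Whitney
pair-counting statistic (asserted exhaustively for up to 8 channels). The
channel — not the segment — is the statistical unit.

## Synthetic data: what it emulates and what it does not

`generate_recording` builds each channel as unit-RMS background noise plus
Gabor atoms (Gaussian-windowed sinusoids, ~50 ms, the standard HFO surrogate)
at Poisson onset times, carrier frequency uniform over the ripple or
fast-ripple band (equal mix). Defaults: pink (1/f) background flattened below
2 Hz — real EEG spectra plateau at the lowest frequencies, and an unbounded
1/f tail would let a handful of near-DC bins dominate each channel's total
power; SOZ burst rate 12/min vs 1/min elsewhere (interictal HFOs outside the
SOZ are rare, order one per minute); burst SNR 3, defined as atom RMS over
its nominal duration divided by the channel's background RMS inside the
atom's own band, so detectability is independent of the noise color.
`generate_cohort` jitters channel and SOZ counts around a base specification
with per-patient seeds derived from one cohort seed.

The generator reproduces the *rate asymmetry* structure of the clinical
problem, not its physiology: no spike-and-wave morphology, no electrode
geometry or montage correlation, no artifacts, no non-stationarity across the
hour. Passing the end-to-end tests therefore shows the pipeline correctly
turns band-limited rate asymmetries into channel rankings — it does not
certify clinical performance, which the original recordings (unavailable
publicly) would be needed to assess.

## Test and acceptance problem sizes

The end-to-end acceptance test uses five one-hour 20-channel (3 SOZ)
recordings at 2 kHz under generator defaults — about two minutes of compute
per recording with the vectorized feature path — and checks channel AUC
≥ 0.95 per recording with cohort-mean segment sensitivity ≥ 70% and
specificity ≥ 90%. The null calibration (equal burst rates everywhere) uses
three 20-minute recordings and checks the cohort-mean AUC lies in [0.2, 0.8];
the mean is used because a single null recording's AUC with 3 positive vs 17
negative channels has a standard deviation near 0.19 under the null, so a
per-recording band that wide would still be violated by chance about one run
in ten. `scripts/acceptance.py` uses a three-recording high-SNR cohort and a
two-recording null cohort to stay well inside a few minutes of compute while
reporting the same quantities.

## Known limitations

* EDF reading requires the optional `mne` dependency; EDF writing is not
  provided (the matrix + JSON-sidecar format is the round-trip format).
* The binned MI estimator is biased upward for small samples; with the
  default 10 bins and ≥ 1000 training rows the bias is far below the
  between-column differences that drive the rankings, but rankings from very
  short recordings should be treated with caution.
* Features are scale-dependent (Var, RMS, ...); recordings must use
  consistent physical units across channels. This is documented, not
  enforced.
* The patient-dependent design trains and tests within one recording; the
  package loops recordings independently and does not implement pooled
  cross-patient training.
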