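# Methods

This note records the modeling assumptions, parameter choices and
numerical conventions behind the package, and what the synthetic-data
experiments do and do not demonstrate.

## Problem setting

Scalp EEG from epilepsy patients cycles through interictal (baseline),
preictal (the window before a seizure onset), ictal and postictal states.
Seizure *prediction* is the binary classification of fixed-length EEG
windows into preictal vs interictal; ictal and postictal data are
excluded.  The preictal horizon is 30 minutes before onset with no gap
between the horizon's end and the onset.  Windows are 15 s, non-
overlapping, at 256 Hz (3840 samples); trailing partial windows are
discarded so all segments are equal-sized.

Labeling is deliberately conservative: a window is preictal only if it
lies *entirely* inside the horizon (no partial overlap, avoiding
ambiguous edge labels), its session contains the onset, and the previous
session was seizure-free (so postictal activity cannot masquerade as
preictal).  Interictal windows must come from sessions with no seizure
within two sessions on either side.  Everything else is unlabeled and
dropped from training and evaluation.

## Denoising

A fixed three-stage chain, each stage independently switchable:

1. **Butterworth band-pass 0.5–40 Hz, order 4, zero-phase.**  The cutoffs
   bracket the clinically relevant delta-to-low-gamma range and reject
   drift and mains interference.  The order and phase handling are our
   choices: order 4 is the common EEG default, and forward–backward
   application (`sosfiltfilt`) avoids phase distortion of the features at
   the cost of an effectively doubled order.
2. **Wavelet shrinkage, db4, 5 levels, universal soft threshold.**  The
   noise scale is estimated per channel as MAD(finest details)/0.6745 and
   all detail levels are soft-thresholded at `σ̂·√(2 ln N)`.  db4/level-5
   is the standard EEG wavelet-denoising configuration; a zero estimated
   threshold degenerates gracefully into plain decompose/reconstruct.
3. **Fourier masking.**  Real-FFT bins strictly outside 0.5–40 Hz are
   zeroed.  The mask is idempotent and exactly preserves bin-aligned
   in-band tones.

Filtering is applied per segment after segmentation (the pipeline's data
flow hands segments, not sessions, to the denoiser).  Denoising is
stateless, so it is computed once outside the cross-validation folds.

## Channel reduction

Channels are scored by two criteria: pooled population variance
(`(1/K) Σ (x−μ)²` over all provided samples — higher variance read as
more brain activity) and a signal-quality index.  The SQI used here is
the fraction of periodogram power inside 0.5–40 Hz; the original notion
of signal quality this stands in for is cited in the literature without a
definition, so the in-band power fraction was chosen as a simple,
monotone, unit-free proxy, and the selection function accepts any
alternative scoring callable.  The two criteria are combined by rank sum
(smaller is better) with ties broken toward the lower channel index;
rank-sum combination is likewise our choice, since only the criteria
themselves, not their combination, are prescribed.  The default
`n_select = 5` mirrors the five-channel illustrations that motivated the
selection stage.

The surrogate channel is either the pointwise channel mean (an averaging
filter that raises SNR by √n for independent noise) or the projection
onto the leading common-spatial-patterns filter.  CSP is computed from
trace-normalized average class covariances via the symmetric-definite
pencil `(C_pre, C_pre + C_inter)`, so eigenvalues lie in [0, 1] and
measure relative preictal variance; the filters jointly diagonalize both
class covariances and satisfy `W (C_pre + C_inter) Wᵀ = I`.  A singular
composite covariance is regularized by `ε·I` with
`ε = 1e-8 · trace/dim` and a logged notice.  Because CSP is supervised,
it is fit on training folds only; fitting it on all data would leak
labels into the test fold.  Only the single leading filter is used (the
"optimal spatial filter"); multi-filter CSP feature vectors are out of
scope.

## Features

Nine handcrafted statistics per single-channel window: min, max, mean,
variance, standard deviation and skewness in the time domain; spectral
centroid, spectral variance and spectral skewness of the PSD.  Moment
conventions: population normalization (1/K); standard deviation is
√variance; skewness is standardized (third central moment / σ³) and 0 by
convention for a constant signal.  The standardized form is required for
the values to be dimensionless and of order 0.1–1 at volt-scale signals;
the raw third moment would be ~1e-15.  Spectral moments are
power-weighted moments of the frequency grid *in Hz* (so the centroid is
a physical frequency in the 5–25 Hz range for EEG); the zero-frequency
bin is excluded, spectral skewness is 0 when the spectral variance
vanishes, and a zero-power spectrum is rejected explicitly.  The PSD
estimator is the periodogram of the mean-removed window (Parseval holds:
integrated density = variance), with Welch available when estimate
variance matters more than exactness.

CNN features are the global-average-pool activations (512-wide at full
width).  Fusion concatenates `[handcrafted(9) | cnn(512)]` into a
521-vector, each block z-scored with training-set statistics only.

## The 1-D CNN

Stack: conv(32,k3) → batchnorm → leaky-ReLU(0.01) → maxpool(2) →
conv(64,k3) → leaky-ReLU → maxpool(2) → dropout(0.5) → conv(128,k3) →
leaky-ReLU → avgpool(2) → dropout(0.5) → conv(256,k3) → leaky-ReLU →
avgpool(2) → conv(512,k3) → leaky-ReLU → global-avgpool → dense(1,
sigmoid).  Convolutions are valid-padded, stride 1; pooling floors odd
lengths.  Parameter counting: conv `filters·(in·kernel + 1)`, batchnorm 4
per channel (scale, shift and both running statistics — the convention
under which the published per-layer counts and the 524,449 total
reproduce exactly), dense `in + 1`.

The published configuration implies 6 input channels and input length
5120 (both forced by the table arithmetic: 608 = 32·(6·3+1) and
5118 = 5120−2), which does not match the pipeline's single surrogate
channel of 3840 samples; the discrepancy is left unreconciled upstream,
so both configurations are supported — 6 × 5120 exists for architecture
verification, and the pipeline runs 1 × 3840.  For CPU-scale training the
filter banks can be narrowed proportionally (default reduced width
4/8/16/32/64, giving 64-wide features); the layer sequence and all
verification arithmetic are unchanged.

Training: binary cross-entropy, Adam at 1e-3, batch 32, 50 epochs by
default (10 in the reduced pipeline configuration), stratified 20%
validation split, seeded init/shuffling/dropout (identical data + config
+ seed gives bit-identical parameters).  Inputs are standardized by
global training-set mean/scale inside the model — volt-scale inputs would
otherwise give vanishing activations.  History entries are end-of-epoch
evaluations (dropout off).  Inference is dropout-free and deterministic.
The network runs on a small numpy engine written for this package
(forward/backward for conv, batchnorm, pooling, dropout, GAP, dense;
gradients verified against finite differences in the test suite).

## Class balancing

SMOTE: synthetic = `x + u·(x_nn − x)`, `u ~ U[0,1]`, `x` a seeded-random
minority row, `x_nn` one of its k = 5 nearest minority neighbors
(Euclidean) — a coordinatewise convex combination of the two parents.
SPIDER is implemented as prototype perturbation: seeded k-medoids picks
representative minority rows and synthetics add Gaussian noise scaled per
coordinate by 0.1 × the within-class standard deviation.  (The
prototype-perturbation reading follows the originating description;
it differs from the older "selective preprocessing" algorithm that
shares the acronym.)  Real rows are never modified or removed;
`oversample_to_parity` appends synthetics until class counts are equal.
Fidelity of synthetic waveforms is quantified by Pearson correlation and
exact O(nm) dynamic-time-warping distance.

Oversampling operates on feature vectors and is fit inside training folds
by default.  A `balance_before_split` switch instead balances and fits all
transforms before splitting — the order some published protocols describe
— and is intentionally flagged by the leakage audit.

## Stacked ensemble and evaluation

Base classifiers: RBF-kernel SVM (Platt-calibrated scores), 150-tree
random forest, and a 32-unit LSTM.  The LSTM consumes each static fused
vector as a length-1 sequence (the sequence axis is otherwise
unspecified for fused features); with one step the forget gate is inert
and the cell reduces to a gated nonlinear readout, trained with the same
numpy engine.  Stacking follows the classic recipe: the training set is
split stratified 75/25 into D_train (bases) and D_meta; meta-instances
are the base-score 3-vectors `z = [p_svm, p_rf, p_lstm]`; the
meta-learner (default: logistic regression, a small recurrent meta
available) is trained only on D_meta.  Predictions threshold the meta
score at 0.5.

Metrics: confusion counts at the threshold; accuracy, sensitivity
(= TP/(TP+FN), preictal positive) and specificity (= TN/(TN+FP)) in
percent; MCC by its closed form (0 when a marginal vanishes); ROC-AUC by
trapezoidal integration over score thresholds (cross-checked against an
independent implementation in the tests); FP/(FP+TN); and false alarms
per interictal hour when hours are supplied.  Single-class truth makes
AUC undefined; it is reported missing with a notice.

Cross-validation is stratified k-fold (default k = 5) at segment level.
Every supervised component — oversampler, CSP, scaler, CNN, bases, meta —
is fit per training fold, and each fold records the row indices each
component saw; `audit_leakage` asserts these are disjoint from the test
fold.

## Synthetic data generator

Each channel is a sum of four band oscillations (delta 2 Hz, theta 6 Hz,
alpha 10 Hz, beta 21 Hz) with per-segment log-normal amplitude jitter
(σ = 0.25) and random phases, plus 1/f noise synthesized by spectral
shaping of white noise at 0.7 × the oscillatory RMS.  Amplitudes are at
the 1e-5–1e-4 V scale of scalp EEG.  The two classes differ in exactly
two controlled ways, matching the direction of the empirical
preictal/interictal feature contrast: preictal windows have lower
broadband amplitude (segment variance ~1e-9–1e-10 vs ~1e-8 V² interictal)
and oscillatory weight shifted toward the slow bands (spectral centroid
roughly 4–8 Hz vs 12–20 Hz).  `class_separation` interpolates band
amplitudes geometrically between the interictal baseline and the full
preictal shift, so 0 makes the classes draws from literally the same
distribution (the null for chance-level checks), 1 is the default
contrast, and larger values exaggerate it.  Recordings follow a seizure
schedule (samples in the 30 min before an onset are preictal); blink,
muscle-burst and 50 Hz line artifacts can be injected at Poisson rates.
All output is a pure function of (config, schedule, seed).

What the generator does *not* emulate: ictal waveform morphology
(scheduled seizure spans are filled with interictal-statistics signal),
spatial correlation structure across electrodes, non-stationarity beyond
segment-level amplitude jitter, patient-to-patient variability, and real
artifact morphology.  Consequently, passing synthetic-data tests shows
that the pipeline's machinery is correct and leak-free and that it
recovers class structure of the kind the generator encodes — not that
the published clinical performance is reproduced.  Published real-data
results are additionally mutually inconsistent across their own summary
tables, so no real-data target is asserted anywhere in this package.

## Study conditions and problem sizes

The end-to-end checks run 200 segments/class, 23 channels, the
reduced-width CNN at 10 epochs, and stratified 5-fold CV — the package's
chosen desk-scale configuration — once at class separation 3.0 ("high
separation": the parameter-recovery condition, expecting ≥95% mean
sensitivity and specificity) and once at 0.0 (the null, expecting
chance-level accuracy in [40%, 60%]).  Oracle-equivalence checks use 50
random ≤6-channel covariance problems (CSP), 50 random 64-sample signals
(feature moments), 500 synthetic SMOTE points, and all 1,225 confusion
matrices with per-cell counts below 6.

## Known limitations

* DTW is the exact quadratic dynamic program; it is meant for
  segment-scale fidelity checks, not bulk nearest-neighbor search.
* The numpy training engine is single-threaded and float32; it is sized
  for the reduced pipeline configuration, and full-width 6 × 5120
  training, while functional, is slow.
* Subject-wise (grouped) cross-validation is available only as
  segment-level stratification here; clinical evaluation would require
  leave-one-subject-out protocols and alarm post-processing, both out of
  scope.
* EDF writing supports plain 16-bit EDF with whole-second durations and a
  uniform rate; EDF+ event channels and BDF are not supported.
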