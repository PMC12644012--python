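# Methods

This note documents the models, numerical choices and limitations behind
szpipe, in the spirit of a package reference manual. Everything stated here
is computed by the test suite or the example scripts; nothing is quoted
from external runs.

## Signal model and preprocessing

EEG segments are real matrices (channels × timepoints, µV) with a sampling
rate and a class label (ictal / interictal / healthy / unlabeled).
Preprocessing is a Butterworth band-pass whose order-n prototype satisfies
|H(jω)|² = 1/(1 + (ω/ω_c)^{2n}) at each cutoff; the default spec is order 5,
0.5–60 Hz, which removes drift and mains interference while keeping the
clinically relevant bands. Filtering is zero-phase by default
(forward–backward application, squaring the magnitude response) because
phase distortion shifts spike morphology; a strict single-pass mode is
available (`FilterSpec(zero_phase=False)`), and the single-pass magnitude
at the designed cutoffs is exactly 1/√2 (verified against the analytic
bilinear-design formula in the tests). Filters are applied to continuous
recordings before windowing, so window edges see no extra transients.

Windowing follows the usual clinical bookkeeping. Ictal: 2-s sliding
windows with a 1-s step inside each annotated seizure; durations are
treated as whole seconds (fractional ends floored), so an L-second seizure
yields L−1 windows and a set of seizures yields Σ(L_i−1) — e.g. 7 seizures
totalling 442 s yield exactly 435 windows. Interictal: non-overlapping 2-s
epochs at least `gap_s` (default 4 h) from every seizure boundary.
Intervals are half-open [t, t+2) with 0-based sample indexing, which makes
ictal windows and interictal epochs provably disjoint.

EDF support is deliberately narrow: continuous recordings with one uniform
per-channel rate (mixed-rate and EDF+D files are rejected rather than
resampled). Reading goes through mne; writing (for fixtures) is a minimal
in-package 16-bit writer with 1-s records and µV calibration, whose
round-trip error is bounded by the 16-bit quantization step.

## Features

Each channel of a window is decomposed with a five-level db4 DWT
(PyWavelets) into A5, D5…D1; band edges follow dyadic halving, e.g.
0–2.713 Hz for A5 at 173.61 Hz and 64–128 Hz for D1 at 256 Hz. Features are
computed on the coefficient sequences directly rather than on
band-reconstructed signals — cheaper, conventional, and order-preserving
for the class contrasts the classifier uses. Per sub-band: MAV, population
STD (divisor N, not N−1), total band power via a boxcar periodogram whose
bins satisfy Parseval's identity (so the value equals mean(x²) to machine
precision), and fuzzy entropy.

Fuzzy entropy uses the standard template formulation: mean-centred
m-length windows, Chebyshev distances, exponential membership
exp(−(d/r_abs)^grad), with φ_m and φ_{m+1} the mean pairwise similarity
over the same n−m templates (self-matches excluded), and
FuEn = ln φ_m − ln φ_{m+1}. Defaults m = 2, r = 0.2 (fraction of the
segment SD), grad = 2 — the field-standard parameterization. A constant
input short-circuits to 0. The vectorized implementation is pinned to a
literal double-loop oracle at 1e−10.

Min-max normalization to [0, 1] is always fitted on training rows only and
applied to test rows without clipping (out-of-range test values are
informative, and clipping would hide scale drift); constant columns map to
0 with a warning.

## Two-stage balancing

Stage 1 (cluster-centroid under-sampling) runs k-means
(k-means++ initialization, single restart, ≤300 iterations, seed 42) on the
majority class with k = round(n_min / under_strategy); the centroids
replace the majority rows. With the default strategy 0.5 this leaves
exactly a 2:1 majority:minority ratio. If the requested retention is not
below the current majority count the stage is a no-op (already balanced
input passes through unchanged).

Stage 2 is Borderline-SMOTE variant 1. Minority points are classified by
the composition of their m = 10 nearest neighbours in the whole training
set (Euclidean, self excluded, distance ties broken by lower row index):
*noise* if all m are majority, *danger* if at least m/2 but fewer than m,
*safe* otherwise. Synthetic rows interpolate danger points toward their
k = 5 nearest minority neighbours, s = p + γ(q − p), γ ~ U[0, 1], with the
total count round(over_strategy · n_maj) − n_min spread as evenly as
possible over the danger rows (remainder to the lowest-index ones). An
empty danger set falls back to plain SMOTE over all minority rows with a
prominent warning (`strict_danger=True` turns this into an error) so that
small, well-separated fixtures still run. Every synthetic row lies inside
the minority bounding box and on a segment between its two parents —
both asserted in tests.

Balancing operates in normalized feature space, on training folds only;
`FeatureTable.role` is checked so a test table can never be balanced, and
row provenance (original / centroid / synthetic) is carried through for
leakage auditing.

## CSAE-GRU

The networks are a compact NumPy implementation (float64, explicit
backprop, Adam) — at these problem sizes (feature vectors of 24–552
dimensions, batches of 32) this is fast, exactly reproducible, and every
gradient is pinned by central finite differences at 1e−4 relative
tolerance (with a 1e−6 absolute floor: a conv bias feeding batch-norm is an
exact null direction, where only cancellation noise remains).

Encoder: conv(3×1, same padding) → batch-norm → ReLU → dropout 0.2, twice,
channels 1→32→16. Decoder mirrors with 16→16→1 and a linear regression
layer (no dropout in the decoder). Loss per sample is
‖x − x̂‖₂² + λ‖h‖₁, averaged over the batch; λ defaults to 1e−4 and its
sparsity pressure is verified as weakly monotone (mean |h| non-increasing
over λ ∈ {0, 1e−3, 1e−2} on a seeded fixture). Pretraining: Adam lr 0.001,
batch 32, ≤30 epochs, early stop when the epoch-mean per-feature squared
reconstruction error falls below `recon_stop_threshold` (default 1e−3).

Transfer: the encoder's conv and batch-norm layers are deep-copied into
the classifier (dropout dropped), frozen by default — including batch-norm
statistics, which stay in eval mode even when fine-tuning is enabled. The
16×D latent map is read as a sequence of D steps with 16-dim inputs for a
GRU with 64 hidden units; this is the reading that gives the GRU a
non-trivial sequence. A strict flatten mode (`scalar_sequence=True`,
length 16·D of scalar steps) is available behind a flag. The final hidden
state passes dropout 0.5 and a dense(2) softmax head; training is
cross-entropy with Adam, ≤50 epochs, batch 32. Class index 1 is ictal
everywhere — sensitivity and specificity swap otherwise. Prediction
requires a normalized table (a raw table raises), argmax ties resolve to
class 0, and checkpoints round-trip bit-exactly through a single `.npz`
archive.

Weight initialization is the uniform fan-in scheme U(±1/√fan_in), seeded;
all shuffling, dropout and initialization derive from integer seeds, so two
identical-seed runs produce byte-identical metrics files.

## Evaluation protocol

Confusion-count metrics follow the standard definitions; degenerate 0/0
denominators return 0 with a warning so fold reports stay well-formed. AUC
is the trapezoidal area over all score thresholds and equals the
tie-corrected Mann-Whitney statistic U/(n₁n₀) (pinned at 1e−12). Two
evaluation modes exist because both are standard: a stratified 80/20
holdout and stratified fivefold cross-validation (the headline mode); fold
AUCs are averaged arithmetically. Inside each training fold the runner
fits the normalizer, balances, pretrains the CSAE and trains the
classifier; the test fold keeps its natural imbalance and is only ever
normalized with the training map.

## Synthetic data

The generator emulates the two-class contrast that drives seizure
detectors, not physiological EEG. Interictal windows are band-limited
(0.5–30 Hz) noise — white by default, 1/f pink optionally — scaled to
`amp_interictal` (default 10 µV RMS). Ictal windows add a discharge of
three stereotyped ingredients: a 3 Hz spike-wave rhythm (fundamental with
two harmonics and one ~20 ms transient per cycle), broadband
(0.5 Hz–0.45·fs) fast activity (amplitude fraction 0.45), and an 18–24 Hz
beta "recruiting" oscillation (fraction 0.3). The discharge RMS is
sqrt(amp_ictal² − amp_interictal²), so the total RMS is `amp_ictal`
(default 60 µV) and the classes coincide continuously as amp_ictal →
amp_interictal — the tests exploit this dial to show end-to-end accuracy
falling from ≥0.95 toward chance at a near-unit amplitude ratio. The beta
component is what makes the D3-band fuzzy entropy of ictal windows exceed
interictal: wavelet coefficients of any smooth-spectrum noise are
near-white (an entropy ceiling), while a critically-sampled in-band
oscillation raises template-level irregularity in coefficient space.

Generation is a pure function of `SynthConfig`: each segment draws from a
counter-based sub-seed (seed, class, index), so datasets are reproducible
and order-independent. The default corpus — 1,000 interictal vs 17 ictal
2-s single-channel windows at 256 Hz (~59:1) — is the study condition used
by the acceptance suite. What passing tests show is therefore that the
pipeline machinery (windowing arithmetic, leakage-safe balancing, transfer,
metrics) is correct and that the classifier separates classes whose
feature-space contrast resembles published ictal/interictal separations;
they do not certify performance on real EEG, which carries artifacts,
non-stationarity, inter-patient variability and annotation noise the
generator does not model.

## Problem sizes and runtime

The test-bench scales were chosen so the whole suite runs in about a
minute on one CPU: the headline cross-validation uses the full 1,000/17
corpus; balancing count contracts are asserted at 2,000×435 (the
870-centroid k-means is the dominant cost of that test); the determinism
(byte-identity) check reruns the full pipeline on a 120/12 corpus, since
seed-driven determinism is size-independent.

## Known limitations

- No artifact rejection, montage handling, re-referencing or ICA; EDF
  support excludes mixed-rate and discontinuous files.
- The CHB-MIT-native "summary" annotation grammar is not parsed; seizure
  annotations come from a plain `recording,start_s,end_s` CSV.
- Borderline-SMOTE variant 2 (interpolation toward majority neighbours) is
  not implemented.
- The NumPy networks are CPU-bound and single-threaded by design; they are
  sized for feature-vector inputs, not raw-waveform deep learning.
- Binary ictal/interictal detection only; no multi-class seizure typing.
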