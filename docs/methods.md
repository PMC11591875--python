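# Methods

This document records the models, parameter choices, numerical decisions and
problem sizes used by `coughkit`, and the realism limits of its synthetic
data generator.

## Task and data model

The task is cough sound event detection in long, mostly quiet clinical-style
audio: mono PCM WAV at 22,050 Hz plus Audacity-style label tracks
(`start_s<TAB>end_s<TAB>label`) marking cough, speech, laugh and throat-clear
events. The analysis unit is a non-overlapping 0.5-s window; a window is
labeled positive when it overlaps a cough annotation by at least 0.1 s (or
half the annotation's duration for very short coughs — a rule this package
defines, since "contains a cough" is otherwise ambiguous).

Two preprocessing tracks exist:

* **CRNN track** — all windows, unfiltered. The class imbalance (raw positive
  fraction is typically below 5%) is handled in the loss.
* **Baseline track** — the amplitude imbalance filter first drops every
  negative window whose mean absolute amplitude falls below the
  recording-wide mean (positives are always kept), raising the positive
  fraction into the ~10–15% range; features are then flatten (128×22 → 2816)
  → PCA retaining 95% variance → per-component standardization, fitted on
  the training split only.

Silence trimming (`trim_silence`) exists as an annotation-effort utility and
is deliberately **not** part of either training track.

## Synthetic generator

Real clinical cough recordings are private, so every experiment runs on
synthetic corpora with the same statistical structure:

* **Coughs** are band-passed white noise (2nd-order Butterworth, 300–4000 Hz)
  under a fast-attack (~10 ms) exponential-decay envelope, with a weaker
  second burst phase 80 ms after onset. Coughs arrive in Poisson-placed
  bouts of 1–4 bursts whose peaks decay geometrically (factor 0.75) across
  the bout, matching the clinical observation that later coughs in a bout
  are quietest.
* **Distractors** are a harmonic stack with slow amplitude modulation
  (speech-like, F0 100–250 Hz) and paired low-band bursts (throat clear).
* **Noise floor**: Gaussian noise at a configurable level relative to the
  first-cough peak (−45 dB by default), with a slow level wander (±3 dB std,
  control points every 2 s, linearly interpolated in dB). The wander is a
  realism requirement, not decoration: with a perfectly stationary floor,
  every quiet window has almost exactly the global mean amplitude and the
  amplitude filter degenerates (it removes essentially all negatives). Real
  room noise is non-stationary; with the wander the filter behaves as
  intended.
* **Environments**: the default corpus has three subsets A/B/C with graded
  noise floors (−45/−35/−22 dB) and distractor rates (0.5/1/2 per minute),
  emulating recordings from three rooms of increasing difficulty.

At the default regime (600 s, 2 bouts/min of 1–4 coughs) the raw positive
window fraction is ~3.5–5%, and ~12–15% after filtering.

**Known limits.** The cough model is acoustic shorthand, not physiology: no
vocal-tract resonances, no room impulse response, no speaker variability.
Crucially, the *same* cough waveform model is used in all three environment
subsets — only the background differs — so cross-environment experiments
probe robustness to noise, not to domain shift in the coughs themselves (see
"Cross-environment validation" below).

## Features

STFT with n_fft = 2048, hop = 512, centered frames, Hann window — the unique
common configuration that maps an 11,025-sample window to exactly 22 frames.
A 128-band Slaney-style Mel filter bank (linear below 1 kHz, logarithmic
above; triangular, equal-area normalized) gives the (128, 22) grid; energies
are expressed in dB relative to the segment's own maximum and clipped to an
80-dB range, so values lie in [−80, 0] and an all-zero segment is a uniform
0-dB grid. MFCC (DCT-II, orthonormal, first 13 of the dB-Mel energies),
zero-crossing rate and spectral roll-off are computed and exposed but not
wired into the CRNN input.

Numerical notes: spectral roll-off of a silent frame is 0 Hz by convention;
the roll-off of a pure tone lands within ~2 FFT bins (≈22 Hz) of the tone
rather than 1 because Hann leakage spreads energy into neighboring bins.
PCA standardization happens *after* the projection (PCA then StandardScaler),
which is the order the baseline protocol specifies.

## CRNN

Architecture (input one (1, 128, 22) Mel grid):

* Four residual convolution blocks. Each block: a 1×1 "simple layer"
  projection of the block input is added to the output of the first 3×3
  convolution, then batch-norm + ReLU, a second 3×3 convolution +
  batch-norm + ReLU, then 2× max pooling along the **frequency axis only**.
  Channels double per block: 128 → 256 → 512 → 1024 at reference width;
  frequency shrinks 128 → 8.
* The remaining 8 frequency rows are mean-pooled away, yielding a 22-step
  sequence of 1024-dim features (this scheme is the minimal one consistent
  with a 1024-wide recurrent input; how the grid becomes a sequence is
  otherwise unspecified).
* A 4-layer LSTM (hidden 512, forget-gate bias initialized to 1), the final
  step's top-layer hidden state, a fully connected layer, and a sigmoid.

Loss: class-weighted binary cross-entropy
`L = −mean[w_true·y·log p + (1−y)·log(1−p)]` with `w_true = n_false/n_true`
from the *training* split's class counts, so the positive (minority) class is
up-weighted and the all-negative collapse is not an attractive optimum.
Probabilities are clamped to [1e−7, 1−1e−7] in the reported loss; training
itself uses the numerically stable logits form
`w·y·softplus(−z) + (1−y)·softplus(z)`.

Training: Adam (lr 1e−3), batch 64 (reference) — standard choices, fixed
rather than tuned. Per epoch, metrics are computed on the held-out split and
three checkpoints are maintained: best accuracy, best sensitivity, and best
mixed score (accuracy + sensitivity), exposing the accuracy–sensitivity
trade-off. After `fit`, `CRNNClassifier` restores the checkpoint named by
`restore` (default "mixed").

The network runs on a minimal in-package reverse-mode autodiff engine
(`coughkit._autograd`): numpy tensors with broadcasting arithmetic, im2col
convolution (the input gradient is a correlation with the spatially flipped,
channel-transposed kernel, so both passes share the same matmul path),
axis-restricted max pooling, and Adam. Parameters and activations are
float32; gradients are validated against central finite differences in the
test suite (max relative error ~1e−4).

## Problem sizes (this package's choice)

The reference width (base_filters 128 → 28.9M parameters) is built and
shape-checked, but training experiments run a reduced width on one CPU:
**base_filters 8, LSTM hidden 64**, with the architecture shape (4 residual
blocks, channel doubling, 4 LSTM layers) unchanged. Corpus sizes are
3 × 300 s (test suite) and 3 × 600 s (acceptance script); 6 training epochs
suffice for the separable default regime. These sizes keep the full test
suite under ~8 minutes and the acceptance script under ~12 minutes on a
single CPU while leaving the learning problem non-trivial (1,800–3,600
windows, 3.5–5% positive).

## Baselines

Four scikit-learn classifiers with fixed reference hyperparameters on the
baseline feature track: logistic regression (L2, C=1.0, lbfgs,
max_iter=1000), decision tree (entropy, unlimited depth), random forest
(100 trees, entropy, random_state=42), RBF-kernel SVM (C=1.0, gamma="scale").
ROC scores use predicted probabilities where available, otherwise the signed
decision margin.

## Evaluation

Accuracy, sensitivity (recall on coughs) and specificity from confusion
counts; zero-denominator ratios are reported as absent (`None`) with a
warning, never coerced to 0 or 1. The all-negative reference accuracy is
1 − positive_fraction — on imbalanced data raw accuracy is nearly
meaningless, which is why sensitivity is reported alongside. ROC curves use
every distinct score threshold (plus +∞) so endpoints are exactly (0,0) and
(1,1); AUC is the trapezoid integral and matches the pairwise Mann–Whitney
probability.

### Cross-environment validation

`cross_validate` splits each subset (stratified, 10% test), trains on each
subset's training part and on all pooled, and evaluates every source on
every subset's *test* part — a (k+1) × k matrix whose diagonal is held out
and whose pooled row leaks nothing.

Observed direction on the synthetic corpus: models trained on the clean
subsets A/B transfer poorly **into** the degraded subset C (coughs buried in
a −22 dB floor are missed; A→C sensitivity can be 0), while models trained
on C transfer fine to A/B — noisy training data acts as augmentation, and
the cough waveform model is identical across subsets. So the degraded
environment shows up as worse transfer *into* C rather than worse models
*from* C; the acceptance check asserts that direction (mean mixed score of
{A→C, B→C} well below transfer between the clean pair).

## Weighted vs unweighted loss

On the easy default corpus both loss variants reach sensitivity 1.0, so the
claim "class weighting raises sensitivity" is tested where imbalance
actually bites: a deliberately hard 240-s recording (noise floor −20 dB,
dense bouts of 2–6 coughs, fast amplitude decay 0.55, distractors 1.5/min).
There, over three seeds at 3 epochs, weighted training reaches mean held-out
sensitivity ≈ 0.43 vs ≈ 0.14 unweighted. The regime was chosen by the
criterion "collapse to all-negative must be locally attractive", then
measured once — not tuned against the assertion.

## Reproducibility

Every stochastic component draws from `numpy.random.default_rng` seeded
explicitly: the generator per recording, training shuffles (config seed + 1),
internal validation splits (seed + 2), and the acceptance script derives all
sub-seeds (< 2³¹) from its single `--seed`. Identical seeds give bit-identical
corpora and model parameters.
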