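# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Synthetic tremor cohorts

`alwx.synthetic` emulates multi-site upper-limb tremor recordings during a
drinking action. Each subject is a spectral template rendered to a
time-domain signal per site (lower arm, hand, upper arm):

* **Class templates.** PD subjects carry one dominant narrowband component
  drawn from 4.6–5.6 Hz (bandwidth 0.25 Hz); ET subjects one from
  7.0–10.0 Hz (bandwidth 0.5 Hz). The two pathological bands are kept
  disjoint at cohort scale so the class signatures the interpretation
  stage should recover are well defined. Normal subjects have no
  pathological component; every subject has a ~3.1 Hz voluntary drinking
  component (amplitude 1.0 for N, 0.5 for patients — pathological tremor
  partially masks the voluntary motion) and a broadband 20–30 Hz
  physiological band (amplitude 0.30 for N, 0.06–0.08 for patients,
  i.e. relatively *higher* in normal subjects). Units are arbitrary; only
  ratios matter. Per-subject amplitude factors (patients: uniform
  0.5–1.2) overlap the classes' severities so no single cue is sufficient.
* **Action envelope.** The drinking action has movement phases — reach/
  lift at the start, put-down at the end — of 2.0 s at full amplitude and
  a middle hold attenuated to 5%. All subject-specific oscillations
  (tremor, voluntary, physiological) ride this envelope, since they are
  transmitted through the moving limb; only the white sensor noise
  (SD 0.05) is constant. Class information is therefore concentrated at
  the sequence edges, which is the regime the explanation analyses
  (timestep preservation, edge-concentrated relevance, τ-windowed
  kernels) are designed for. Kinetic/action tremor recorded during a
  reach-hold-return task is the clinical situation this mimics.
* **Durations and timestamps.** Durations are uniform on 25–26 s. The
  spread is deliberately smaller than the movement-phase length: the
  dataset is later trimmed to the shortest sequence by dropping trailing
  timesteps, and this bound guarantees part of the put-down phase remains
  inside the trailing analysis window of every subject. Timestamps carry
  ±25% sub-sample jitter so the resampling stage is genuinely exercised.
* **Cohort composition.** The default cohort is 50 N / 45 PD / 15 ET,
  preserving the clinical rarity of ET; minority oversampling downstream
  compensates. A balanced 50/50/50 cohort is used by the acceptance
  script.

What passing tests on these data do **not** show: robustness to artifact
contamination (coughing, sensor slip), quaternion/gravity effects,
rest-tremor dynamics that persist through the hold, or subtler PD/ET
spectral overlap in the shared 4–6 Hz region — real cohorts are harder
than this generator, and classifier accuracies here (≈1.0) are optimistic
relative to the ~0.8 reported on clinical data.

## Preprocessing

PCHIP interpolation (shape-preserving, no overshoot) resamples each
channel to 200 Hz; a 4th-order Butterworth bandpass (3–30 Hz) is applied
forward-backward so envelope timing is preserved; the STFT uses a Hann
window of 256 samples with reflection padding. Retained bins 4..38 give
35 frequencies at 0.78125 Hz spacing from 3.125 to 29.6875 Hz; three
sites stack to 105 features per timestep. The frame hop is 25 samples
(125 ms) by default, giving ~200-step sequences in which the 2 s movement
phases span ≈16 steps — comparable to the τ = 20 analysis windows; a hop
of 1 sample (5 ms) reproduces the finest realizable frame spacing at this
rate and remains available in the configuration. Magnitudes are kept raw
(no log scaling); the network's batch-normalization layer standardizes
scale downstream.

## Classifier

One bidirectional LSTM layer, 64 units per direction, implemented in
numpy (forward pass, backpropagation through time, Adam) so that every
intermediate activation is available to the relevance engine. The
sequence summary is the forward hidden state at the last timestep
concatenated with the backward hidden state at the first; batch
normalization and 40% dropout precede the fully connected softmax layer.
Training: Adam 1e-3, batch 32, weight decay 1e-4 on weight matrices,
up to 120 epochs with early stopping (patience 20) on validation loss,
10% input-feature dropout as augmentation. The capacity and schedule were
sized so the classifier's internal representation is stable across
training seeds — narrower or shorter-trained networks occasionally learn
cancellation-heavy encodings whose relevance decompositions make poor
linear surrogates — and so that the network tolerates zeroed input
entries, which the erasure analyses require. Splits: a class-balanced
test set of 10 per class (30 total) is isolated first; the remainder is
split 80:20 into training and validation, stratified by class; minority
classes are oversampled with replacement to the majority count in the
training split only.

## Relevance propagation

Affine layers use the ε-stabilized rule with δ = 0, ε = 0.001 and
sign(0) := +1; the stabilizer share in the numerator is divided by the
layer fan-in. Batch normalization is folded into an equivalent
per-feature affine map (frozen running moments) and treated as 105
fan-in-1 layers. Dropout is identity at explanation time. The LSTM uses
the signal-takes-all convention: output/input/forget sigmoids receive
zero relevance; cell relevance at each step splits between f⊙c_prev and
i⊙g under the same stabilized rule (fan-in 2); candidate relevance flows
through the candidate's affine pre-activation onto the inputs and the
previous hidden state, whose relevance rejoins the cell chain. Relevance
is seeded with the target class's softmax probability placed on its
logit; a `seed="logit"` option seeds the raw logit instead, which makes
the propagation exactly conservative for bias-free linear networks and is
what the exact-recovery oracle uses. Conservation audits record the
summed relevance after each stage; leakage comes from biases, the
ε stabilizers, the gate cut-offs and the zero initial state.

## Linear surrogate (ALW)

Kernels average the stabilized element-wise ratio R/(X + s) over the
oversampled (class-balanced) training split — balancing matters because
the 1/D average otherwise scales each class's kernel by its share of the
data. The default stabilizer is 1e-6 times the median nonzero input
magnitude, and (R = 0, X = 0) entries are excluded from the average; both
are configurable. Start and end windows (τ = 20) are computed separately;
the single-kernel variant (leading window only) is retained on the kernel
object. When T = τ the two windows coincide and every entry is counted
twice; this degenerate case is allowed. Scores are inner products of the
kernels with the input windows and the prediction is argmax with ties
broken toward the lowest class index. A known limitation, visible in the
tests' tolerances: ratio weights at low-magnitude entries are
high-variance, and any spurious weight at another class's high-magnitude
bins is amplified at scoring time, so surrogate accuracy trails network
accuracy and varies a few points across training seeds.

## Interpretation analyses

* **Erasure** ranks individual (timestep, feature) entries by the
  predicted-class relevance of each sample, zeroes the top fraction
  (most-positive first, most-negative first, or seeded random), and
  re-evaluates accuracy. Zeroing all negative-relevance entries should
  restore full accuracy; at fraction 1 all strategies coincide.
* **Timestep preservation** zeroes all but the first and last k steps;
  the plateau detector returns the smallest k within a tolerance
  (default 0.02) of the full-preservation accuracy.
* **Quartered signs** encode a kernel weight sequence as four P/N
  symbols: sign before/after the first flip in the start window, then in
  the end window; no flip duplicates the preceding symbol, zero weights
  inherit the previous nonzero sign, later flips are ignored, and an
  all-zero window is reported as U rather than guessed.
* **Summed weights / High–Low tables** sum each feature's kernel weights
  over both windows, normalize across classes by the maximum absolute
  sum (so each feature has at least one class at ±1; all-zero features
  map to 0), label positive sums High and non-positive Low, and mark a
  label unique to its class with an asterisk.
* **Planted-feature recovery** scores the tables against the generator's
  truth at the granularity the generator actually plants: a narrowband
  component is one feature spanning its few bins (aggregated), and the
  broadband physiological band is one band-level feature per site.

## Numerical choices and degenerate inputs

Tie-breaks always favor the lowest class index. sign(0) = +1 everywhere.
The BN rule rejects non-positive running variance; the bandpass rejects
band edges at or above Nyquist and reports the offending rates; splits
reject classes too small to fill the balanced test set, naming the class.
Erasure with fraction 0 is the identity; preservation with k = 0 yields
the all-zero-input prediction (accuracy 1/3 on a balanced test set).
Problem sizes throughout the tests and the acceptance script (cohorts of
110–150 subjects, ~200-step sequences, ≤120 epochs) are the package's
default desk-scale study conditions.
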