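# alwx

Explainable classification of upper-limb tremor: a bidirectional-LSTM
classifier separates normal subjects (N), Parkinson's disease (PD) and
essential tremor (ET) from wearable-sensor recordings; layer-wise relevance
propagation (LRP) attributes each decision to individual time-frequency
inputs; and an **approximate-linear-weights (ALW)** surrogate collapses the
network into two interpretable linear kernels that classify on their own
and expose per-frequency, per-site spectral signatures of each group.

The package is aimed at movement-disorder researchers and methods
developers who want a complete, testable implementation of this
explain-then-simplify pipeline, including a synthetic cohort generator
that emulates the relevant clinical data (drinking-action kinetic tremor:
PD power at 4–6 Hz, ET at 4–12 Hz, normal subjects with a ~3.1 Hz
voluntary component and weak 20–30 Hz physiological tremor), so every
stage runs end-to-end without access to patient data.

## Method

Recordings (lower arm L, hand H, upper arm U; non-uniform timestamps) are
resampled with shape-preserving piecewise-cubic (PCHIP) interpolation,
bandpassed to 3–30 Hz, and turned into short-time Fourier magnitudes: 35
bins on a 0.78125 Hz grid (3.125–29.6875 Hz) per site, stacked into
n = 105 features per timestep. All sequences are trimmed to the cohort's
shortest length T.

A one-layer BiLSTM (64 units per direction) reads the T×105 sequence; the
forward state at t = T and backward state at t = 1 are concatenated, batch
normalized, dropout-regularized and mapped to softmax class scores.

LRP walks the class score back through the network with the
ε-stabilized rule (δ = 0, ε = 0.001)

    R_i = Σ_j (w_ij z_i + (δ b_j + ε sign(z_j)) / N_i)
              / (z_j + ε sign(z_j)) · R_j

and the signal-takes-all convention in the LSTM: gates receive no
relevance; cell relevance splits between the carried state f⊙c and the
candidate i⊙g, and the candidate's affine map carries relevance to the
inputs. The target class's softmax probability is seeded on its logit.

The ALW kernels average the element-wise ratio of relevance to input over
the training data, separately for the first and last τ = 20 timesteps:

    W^start_ntc = (1/D) Σ_d R_{c,d}[t, n] / X_d[t, n],   t ∈ [1, τ]
    W^end_ntc   = same over t ∈ [T−τ+1, T]

Class scores are then plain inner products, S_c = ⟨W^start_c, X_start⟩ +
⟨W^end_c, X_end⟩, with prediction argmax S — a standalone linear
classifier whose weight signs read directly as positive/negative
correlation between a frequency at a site and a class.

Validation analyses: erasure (zero inputs ranked by relevance and watch
accuracy collapse or recover), timestep preservation (keep only the first
and last k steps), quartered sign codes, and High/Low feature tables with
uniqueness markers.

## Worked example

```python
from alwx import (
    CohortConfig, generate_cohort, featurize_cohort, stack_features,
    split_dataset, oversample_minority, BiLSTMClassifier, ALWClassifier,
    alw_fidelity, relevance, LRPConfig, conservation_report,
)

cohort = generate_cohort(CohortConfig(), master_seed=42)   # 50 N / 45 PD / 15 ET
X, y = stack_features(featurize_cohort(cohort))
print("feature tensor:", X.shape)

split = split_dataset(y, seed=1)                 # class-balanced test set of 30
train_ids = oversample_minority(split.train_ids, y, seed=2,
                                forbidden=split.test_ids)
clf = BiLSTMClassifier(random_state=3)
clf.fit(X[train_ids], y[train_ids],
        X_val=X[split.val_ids], y_val=y[split.val_ids])
print("test accuracy:", clf.score(X[split.test_ids], y[split.test_ids]))

surrogate = ALWClassifier(network=clf, tau=20).fit(X[train_ids], y[train_ids])
fid = alw_fidelity(surrogate, clf, X[split.test_ids], y[split.test_ids])
print("ALW accuracy:", round(fid["alw_accuracy"], 3),
      "agreement:", round(fid["agreement_rate"], 3))

rt = relevance(clf, X[split.test_ids], target_class=1, config=LRPConfig())
print(conservation_report(rt).to_string(index=False))
```

Output:

```
feature tensor: (110, 200, 105)
test accuracy: 1.0
ALW accuracy: 0.967 agreement: 0.967
      layer  relevance_sum  leakage
     seeded      10.000453 0.000000
   after_fc      10.009819 0.009366
   after_bn      12.175168 2.174715
input_total      12.177078 2.176625
```

The 110 recordings become 200-step sequences of 105 STFT magnitudes. The
recurrent classifier separates the three groups perfectly at this data
scale; the linear surrogate recovers 96.7% of its test decisions. The
conservation report tracks the summed relevance layer by layer: the seeded
scores (here ~10 over 30 samples — the softmax probabilities of class N)
are nearly conserved through the fully connected layer, while the batch
normalization shifts and the LSTM gate cut-offs leak some relevance, which
is expected of the stabilized rule.

The `alwx` command line chains the same stages
(`alwx simulate | preprocess | train | lrp | alw | interpret | run`), each
reading/writing CSV/NPZ artifacts plus a JSON manifest; see
`alwx --help`.

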