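"""Shared fixtures.

The expensive artifacts — the default synthetic cohort, its STFT features,
and one fully trained classifier with its linear surrogate — are built once
per session and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from alwx import alw as alw_mod
from alwx import network as net
from alwx import preprocess as pp
from alwx import synthetic as syn


@pytest.fixture(scope="session")
def default_features():
    """Default cohort (N=50, PD=45, ET=15; master seed 42) -> stacked features."""
    cohort = syn.generate_cohort(syn.CohortConfig(), 42)
    feats = pp.featurize_cohort(cohort)
    X, y = pp.stack_features(feats)
    return {"X": X, "y": y, "freq_axis": feats[0].freq_axis_hz, "cohort": cohort}


@pytest.fixture(scope="session")
def trained(default_features):
    """Trained classifier + linear surrogate on the default cohort."""
    X, y = default_features["X"], default_features["y"]
    split = net.split_dataset(y, seed=1)
    tr = net.oversample_minority(split.train_ids, y, seed=2, forbidden=split.test_ids)
    clf = net.BiLSTMClassifier(random_state=3)
    clf.fit(X[tr], y[tr], X_val=X[split.val_ids], y_val=y[split.val_ids])
    aclf = alw_mod.ALWClassifier(network=clf, tau=20).fit(X[tr], y[tr])
    aclf.kernel_.freq_axis_hz = default_features["freq_axis"]
    return {
        "clf": clf,
        "aclf": aclf,
        "X": X,
        "y": y,
        "split": split,
        "train_ids": tr,
        "freq_axis": default_features["freq_axis"],
    }


@pytest.fixture()
def tiny_recording():
    """A short clean recording with a single 5 Hz component."""
    profile = syn.SubjectProfile(
        class_label="PD",
        tremor_components=[(5.0, 1.0, 0.0, 0.3)],
        voluntary_component=(3.1, 0.0),
        physiological_band=(20.0, 30.0, 0.0),
        per_part_gain=(1.0, 1.0, 1.0),
        duration_s=10.0,
        reaction_delay_s=0.0,
        noise_sd=0.0,
    )
    return syn.synthesize_recording(profile, "REST", rng_seed=5)


def make_random_bilstm(
    input_size=6, hidden_units=4, n_classes=3, seed=0, zero_bias=False, bn=False
) -> net.BiLSTMClassifier:
    """An untrained (randomly initialized) classifier usable for LRP tests."""
    cfg = net.NetworkConfig(
        input_size=input_size,
        hidden_units=hidden_units,
        n_classes=n_classes,
        dropout_p=0.0,
        input_dropout_p=0.0,
        bn_enabled=bn,
    )
    rng = np.random.default_rng(seed)
    params = net.init_params(cfg, rng)
    if zero_bias:
        for k in ("b_f", "b_b", "fc_b"):
            params[k][:] = 0.0
    clf = net.BiLSTMClassifier.__new__(net.BiLSTMClassifier)
    clf.params_ = params
    clf.config_ = cfg
    clf.bn_state_ = {"mean": np.zeros(2 * hidden_units), "var": np.ones(2 * hidden_units)}
    clf.classes_ = np.arange(n_classes)
    return clf
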