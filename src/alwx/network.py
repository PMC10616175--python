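"""BiLSTM sequence classifier (numpy implementation, sklearn-style estimator).

Architecture: one bidirectional LSTM layer over the T x 105 feature
sequence; the fixed-length summary is the forward hidden state at the last
timestep concatenated with the backward hidden state at the first timestep;
batch normalization standardizes the summary; dropout (default 40%)
regularizes it; a fully connected layer plus softmax produces the three
class probabilities.

Everything — forward pass, backpropagation through time, Adam — is
implemented here on numpy arrays, because the relevance-propagation engine
needs every intermediate activation of the exact network being explained.
Gate pre-activations are stored in i, f, g, o order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .preprocess import FeatureTensor


@dataclass
class NetworkConfig:
    input_size: int = 105
    hidden_units: int = 64  # per direction
    n_classes: int = 3
    dropout_p: float = 0.4
    #: dropout applied to the input features during training (same 40%
    #: probability); trains robustness to zeroed input entries, which the
    #: erasure-based faithfulness analyses rely on
    input_dropout_p: float = 0.1
    bn_enabled: bool = True
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.dropout_p < 1.0 or not 0.0 <= self.input_dropout_p < 1.0:
            raise ValueError("dropout probabilities must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


@dataclass
class SplitSpec:
    """Index triple: class-balanced test set, stratified train/val remainder."""

    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray

    def validate(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if parts[0] & parts[2] or parts[1] & parts[2] or parts[0] & parts[1]:
            raise ValueError("train/val/test indices must be disjoint")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def init_params(config: NetworkConfig, rng: np.random.Generator) -> dict:
    """Glorot-uniform weights; forget-gate bias +1 (standard LSTM practice)."""
    n, h, c = config.input_size, config.hidden_units, config.n_classes

    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-lim, lim, shape)

    params = {}
    for d in ("f", "b"):  # forward / backward direction
        params[f"Wx_{d}"] = glorot((n, 4 * h))
        params[f"Wh_{d}"] = glorot((h, 4 * h))
        bias = np.zeros(4 * h)
        bias[h : 2 * h] = 1.0  # forget gate
        params[f"b_{d}"] = bias
    params["bn_gamma"] = np.ones(2 * h)
    params["bn_beta"] = np.zeros(2 * h)
    params["fc_W"] = glorot((2 * h, c))
    params["fc_b"] = np.zeros(c)
    return params


def _lstm_forward(X, Wx, Wh, b, h_units):
    """Run one direction over X (B, T, n); returns final h and full trace."""
    B, T, _ = X.shape
    H = h_units
    hs = np.zeros((B, T + 1, H))
    cs = np.zeros((B, T + 1, H))
    gates = np.empty((B, T, 4 * H))
    for t in range(T):
        a = X[:, t] @ Wx + hs[:, t] @ Wh + b
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        cs[:, t + 1] = f * cs[:, t] + i * g
        hs[:, t + 1] = o * np.tanh(cs[:, t + 1])
        gates[:, t, :H] = i
        gates[:, t, H : 2 * H] = f
        gates[:, t, 2 * H : 3 * H] = g
        gates[:, t, 3 * H :] = o
    return {"hs": hs, "cs": cs, "gates": gates, "X": X}


def forward(
    params: dict,
    X: np.ndarray,
    config: NetworkConfig,
    train: bool = False,
    bn_state: dict | None = None,
    dropout_rng: np.random.Generator | None = None,
    keep_trace: bool = False,
) -> dict:
    """Full forward pass on a batch (B, T, n). Returns logits, probs, cache."""
    H = config.hidden_units
    if train and config.input_dropout_p > 0:
        keep_in = 1.0 - config.input_dropout_p
        X = X * ((dropout_rng.random(X.shape) < keep_in) / keep_in)
    trace_f = _lstm_forward(X, params["Wx_f"], params["Wh_f"], params["b_f"], H)
    Xr = X[:, ::-1]
    trace_b = _lstm_forward(Xr, params["Wx_b"], params["Wh_b"], params["b_b"], H)
    summary = np.concatenate([trace_f["hs"][:, -1], trace_b["hs"][:, -1]], axis=1)

    cache: dict = {"summary": summary}
    if keep_trace:
        cache["trace_f"], cache["trace_b"] = trace_f, trace_b
    else:
        cache["trace_f"] = {k: trace_f[k] for k in ("hs", "cs", "gates", "X")}
        cache["trace_b"] = {k: trace_b[k] for k in ("hs", "cs", "gates", "X")}

    if config.bn_enabled:
        if train:
            mu = summary.mean(axis=0)
            var = summary.var(axis=0)
            if bn_state is not None:
                m = config.bn_momentum
                bn_state["mean"] = (1 - m) * bn_state["mean"] + m * mu
                bn_state["var"] = (1 - m) * bn_state["var"] + m * var
        else:
            mu = bn_state["mean"]
            var = bn_state["var"]
        inv_std = 1.0 / np.sqrt(var + config.bn_eps)
        x_hat = (summary - mu) * inv_std
        bn_out = params["bn_gamma"] * x_hat + params["bn_beta"]
        cache.update(bn_mu=mu, bn_var=var, bn_inv_std=inv_std, bn_x_hat=x_hat)
    else:
        bn_out = summary

    if train and config.dropout_p > 0:
        keep = 1.0 - config.dropout_p
        mask = (dropout_rng.random(bn_out.shape) < keep) / keep
        do_out = bn_out * mask
        cache["dropout_mask"] = mask
    else:
        do_out = bn_out
    cache["bn_out"] = bn_out
    cache["do_out"] = do_out

    logits = do_out @ params["fc_W"] + params["fc_b"]
    probs = _softmax(logits)
    cache["logits"], cache["probs"] = logits, probs
    return cache


def _lstm_backward(trace, d_h_last, Wx, Wh, h_units):
    """BPTT for one direction given gradient at its final hidden state."""
    X, hs, cs, gates = trace["X"], trace["hs"], trace["cs"], trace["gates"]
    B, T, n = X.shape
    H = h_units
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh = d_h_last.copy()
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H : 2 * H]
        g = gates[:, t, 2 * H : 3 * H]
        o = gates[:, t, 3 * H :]
        c_t = cs[:, t + 1]
        tanh_c = np.tanh(c_t)
        dc = dc + dh * o * (1 - tanh_c**2)
        da = np.empty((B, 4 * H))
        da[:, :H] = dc * g * i * (1 - i)
        da[:, H : 2 * H] = dc * cs[:, t] * f * (1 - f)
        da[:, 2 * H : 3 * H] = dc * i * (1 - g**2)
        da[:, 3 * H :] = dh * tanh_c * o * (1 - o)
        dWx += X[:, t].T @ da
        dWh += hs[:, t].T @ da
        db += da.sum(axis=0)
        dh = da @ Wh.T
        dc = dc * f
    return dWx, dWh, db


def loss_and_grads(
    params: dict,
    X: np.ndarray,
    y_onehot: np.ndarray,
    config: NetworkConfig,
    bn_state: dict | None = None,
    train: bool = True,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[float, dict, dict]:
    """Mean cross-entropy and gradients for every parameter."""
    B = X.shape[0]
    H = config.hidden_units
    if config.dropout_p > 0 and train and dropout_rng is None:
        dropout_rng = np.random.default_rng(0)
    cache = forward(
        params, X, config, train=train, bn_state=bn_state, dropout_rng=dropout_rng
    )
    probs = cache["probs"]
    loss = -np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1))

    grads = {}
    dlogits = (probs - y_onehot) / B
    grads["fc_W"] = cache["do_out"].T @ dlogits
    grads["fc_b"] = dlogits.sum(axis=0)
    d_do = dlogits @ params["fc_W"].T
    if train and config.dropout_p > 0:
        d_bn_out = d_do * cache["dropout_mask"]
    else:
        d_bn_out = d_do

    if config.bn_enabled:
        x_hat, inv_std = cache["bn_x_hat"], cache["bn_inv_std"]
        grads["bn_gamma"] = np.sum(d_bn_out * x_hat, axis=0)
        grads["bn_beta"] = d_bn_out.sum(axis=0)
        dxhat = d_bn_out * params["bn_gamma"]
        if train:
            d_summary = (
                inv_std
                / B
                * (B * dxhat - dxhat.sum(axis=0) - x_hat * np.sum(dxhat * x_hat, axis=0))
            )
        else:
            d_summary = dxhat * inv_std
    else:
        grads["bn_gamma"] = np.zeros_like(params["bn_gamma"])
        grads["bn_beta"] = np.zeros_like(params["bn_beta"])
        d_summary = d_bn_out

    d_hf, d_hb = d_summary[:, :H], d_summary[:, H:]
    grads["Wx_f"], grads["Wh_f"], grads["b_f"] = _lstm_backward(
        cache["trace_f"], d_hf, params["Wx_f"], params["Wh_f"], H
    )
    grads["Wx_b"], grads["Wh_b"], grads["b_b"] = _lstm_backward(
        cache["trace_b"], d_hb, params["Wx_b"], params["Wh_b"], H
    )
    return loss, grads, cache


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * grads[k]
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def split_dataset(
    labels: np.ndarray,
    seed: int = 0,
    test_per_class: int = 10,
    val_fraction: float = 0.2,
) -> SplitSpec:
    """Class-balanced test set (default 10 per class, 30 total for three
    classes); the remainder is split 80:20 into train and validation,
    stratified by class."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    test_ids = []
    for c in classes:
        ids = np.nonzero(labels == c)[0]
        if ids.size < test_per_class + 1:
            raise ValueError(
                f"class {c!r} has only {ids.size} samples; need more than "
                f"{test_per_class} to populate the class-balanced test set"
            )
        test_ids.append(rng.choice(ids, size=test_per_class, replace=False))
    test_ids = np.sort(np.concatenate(test_ids))
    remainder = np.setdiff1d(np.arange(labels.size), test_ids)
    train_ids, val_ids = train_test_split(
        remainder,
        test_size=val_fraction,
        stratify=labels[remainder],
        random_state=int(rng.integers(2**31)),
    )
    spec = SplitSpec(
        train_ids=np.sort(train_ids), val_ids=np.sort(val_ids), test_ids=test_ids
    )
    spec.validate()
    return spec


def oversample_minority(
    train_ids: np.ndarray, labels: np.ndarray, seed: int = 0, forbidden: np.ndarray | None = None
) -> np.ndarray:
    """Duplicate minority-class training samples (with replacement) until
    every class matches the majority count. Never applied outside training."""
    train_ids = np.asarray(train_ids)
    if forbidden is not None and np.intersect1d(train_ids, forbidden).size:
        raise ValueError("oversampling must only be applied to the training split")
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels)[train_ids]
    classes, counts = np.unique(lab, return_counts=True)
    target = counts.max()
    out = [train_ids]
    for c, cnt in zip(classes, counts):
        if cnt < target:
            pool = train_ids[lab == c]
            out.append(rng.choice(pool, size=target - cnt, replace=True))
    return np.concatenate(out)


class BiLSTMClassifier(BaseEstimator, ClassifierMixin):
    """Bidirectional-LSTM tremor-sequence classifier.

    Parameters mirror :class:`NetworkConfig` plus the training loop knobs.
    ``fit`` expects ``X`` of shape (D, T, 105) — equal-length feature
    tensors — and string or integer labels ``y``. Early stopping monitors
    validation loss with the configured patience; pass ``X_val``/``y_val``
    to ``fit`` or let it carve a stratified fraction out of ``X``.
    """

    def __init__(
        self,
        hidden_units: int = 64,
        dropout_p: float = 0.4,
        input_dropout_p: float = 0.1,
        bn_enabled: bool = True,
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        batch_size: int = 32,
        max_epochs: int = 120,
        patience: int = 20,
        val_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.dropout_p = dropout_p
        self.input_dropout_p = input_dropout_p
        self.bn_enabled = bn_enabled
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _validate_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError("X must have shape (D, T, n_features)")
        if hasattr(self, "config_") and X.shape[2] != self.config_.input_size:
            raise ValueError(
                f"expected {self.config_.input_size} features, got {X.shape[2]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must have shape (D, T, n_features)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        C = self.classes_.size
        self.config_ = NetworkConfig(
            input_size=X.shape[2],
            hidden_units=self.hidden_units,
            n_classes=C,
            dropout_p=self.dropout_p,
            input_dropout_p=self.input_dropout_p,
            bn_enabled=self.bn_enabled,
        )
        rng = np.random.default_rng(self.random_state)
        if X_val is None:
            tr, va = train_test_split(
                np.arange(X.shape[0]),
                test_size=self.val_fraction,
                stratify=y_idx,
                random_state=int(rng.integers(2**31)),
            )
            X_val, yv_idx = X[va], y_idx[va]
            X, y_idx = X[tr], y_idx[tr]
        else:
            X_val = np.asarray(X_val, dtype=float)
            yv_idx = np.searchsorted(self.classes_, np.asarray(y_val))

        self.params_ = init_params(self.config_, rng)
        self.bn_state_ = {
            "mean": np.zeros(2 * self.hidden_units),
            "var": np.ones(2 * self.hidden_units),
        }
        opt = _Adam(self.params_, lr=self.lr)
        onehot = np.eye(C)
        y_tr = onehot[y_idx]
        y_va = onehot[yv_idx]
        best_loss, best_params, best_bn, wait = np.inf, None, None, 0
        self.history_ = {"train_loss": [], "val_loss": [], "val_acc": []}
        D = X.shape[0]
        for epoch in range(self.max_epochs):
            order = rng.permutation(D)
            ep_loss = 0.0
            for start in range(0, D, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss, grads, _ = loss_and_grads(
                    self.params_,
                    X[idx],
                    y_tr[idx],
                    self.config_,
                    bn_state=self.bn_state_,
                    train=True,
                    dropout_rng=rng,
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                if self.weight_decay > 0:
                    # decay weight matrices only, not biases or BN parameters
                    for k in ("Wx_f", "Wh_f", "Wx_b", "Wh_b", "fc_W"):
                        grads[k] = grads[k] + self.weight_decay * self.params_[k]
                opt.step(self.params_, grads)
                ep_loss += loss * idx.size
            cache = forward(
                self.params_, X_val, self.config_, train=False, bn_state=self.bn_state_
            )
            val_probs = cache["probs"]
            val_loss = -np.mean(np.sum(y_va * np.log(val_probs + 1e-12), axis=1))
            val_acc = float(np.mean(val_probs.argmax(1) == yv_idx))
            self.history_["train_loss"].append(ep_loss / D)
            self.history_["val_loss"].append(float(val_loss))
            self.history_["val_acc"].append(val_acc)
            if val_loss < best_loss - 1e-6:
                best_loss, wait = val_loss, 0
                best_params = {k: v.copy() for k, v in self.params_.items()}
                best_bn = {k: v.copy() for k, v in self.bn_state_.items()}
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_params is not None:
            self.params_, self.bn_state_ = best_params, best_bn
        self.n_epochs_ = len(self.history_["train_loss"])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        X = self._validate_X(X)
        out = []
        for start in range(0, X.shape[0], 256):
            cache = forward(
                self.params_,
                X[start : start + 256],
                self.config_,
                train=False,
                bn_state=self.bn_state_,
            )
            out.append(cache["probs"])
        return np.concatenate(out)

    def decision_function(self, X):
        check_is_fitted(self, "params_")
        X = self._validate_X(X)
        cache = forward(
            self.params_, X, self.config_, train=False, bn_state=self.bn_state_
        )
        return cache["logits"]

    def predict(self, X):
        # ties broken toward the lowest class index (argmax convention)
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def class_scores(network: BiLSTMClassifier, feature_tensor) -> np.ndarray:
    """Softmax class probabilities for one feature tensor."""
    X = feature_tensor.X if isinstance(feature_tensor, FeatureTensor) else feature_tensor
    return network.predict_proba(np.asarray(X)[None] if np.asarray(X).ndim == 2 else X)[0]


def evaluate(classifier, X, y) -> dict:
    """Accuracy, F1, sensitivity and specificity, one-vs-rest per class.

    ``classifier`` is anything with ``predict`` (the recurrent network or
    the linear-kernel surrogate).
    """
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty test set")
    y_pred = classifier.predict(X)
    return metrics_from_predictions(y, y_pred, classes=np.unique(y))


def metrics_from_predictions(y_true, y_pred, classes=None) -> dict:
    from sklearn.metrics import confusion_matrix, f1_score

    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    total = cm.sum()
    out = {"accuracy": float(np.trace(cm) / total), "confusion_matrix": cm, "classes": classes, "per_class": {}}
    f1s = f1_score(y_true, y_pred, labels=classes, average=None, zero_division=0)
    for k, c in enumerate(classes):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) else 0.0
        spec = tn / (tn + fp) if (tn + fp) else 0.0
        out["per_class"][str(c)] = {
            "accuracy": float(sens),  # per-class accuracy == recall, one-vs-rest
            "f1": float(f1s[k]),
            "sensitivity": float(sens),
            "specificity": float(spec),
        }
    return out
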