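"""Approximate linear weights (ALW): a linear surrogate of the network.

The surrogate collapses the trained recurrent classifier into two linear
kernels per class — one over the first tau timesteps of a sequence and one
over the last tau — by averaging, over training samples, the element-wise
ratio of input relevance to input value:

    W^start[n, t, c] = (1/D) sum_d R_{c,d}[t, n] / X_d[t, n],  t in [1, tau]
    W^end[n, t, c]   = same over t in [T - tau + 1, T]

Class scores are then the plain inner product of the kernels with the
corresponding input windows,

    S_c = <W^start_c, X[1:tau]> + <W^end_c, X[T-tau+1:T]>,

and the prediction is argmax(S) — no further classifier is involved. Two
windows (rather than the single leading-tau kernel) are used because the
bidirectional recurrence concentrates relevance at both sequence ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import lrp as lrp_mod
from .network import BiLSTMClassifier, metrics_from_predictions
from .preprocess import FeatureTensor


@dataclass
class ALWKernel:
    """Start/end window kernels, each of shape (n, tau, C)."""

    W_start: np.ndarray
    W_end: np.ndarray
    tau: int
    classes: np.ndarray
    D_used: int
    ratio_stabilizer: float
    freq_axis_hz: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.W_start.shape[0]

    @property
    def n_classes(self) -> int:
        return self.W_start.shape[2]

    #: single-kernel variant (leading-tau window only), kept alongside the
    #: two-window form; scores from it use only the sequence start
    W_single: np.ndarray | None = None

    def save(self, path) -> None:
        np.savez(
            path,
            W_start=self.W_start,
            W_end=self.W_end,
            tau=self.tau,
            classes=self.classes,
            D_used=self.D_used,
            ratio_stabilizer=self.ratio_stabilizer,
            freq_axis_hz=self.freq_axis_hz if self.freq_axis_hz is not None else np.array([]),
        )

    @classmethod
    def load(cls, path) -> "ALWKernel":
        with np.load(path, allow_pickle=False) as z:
            fa = z["freq_axis_hz"]
            return cls(
                W_start=z["W_start"],
                W_end=z["W_end"],
                tau=int(z["tau"]),
                classes=z["classes"],
                D_used=int(z["D_used"]),
                ratio_stabilizer=float(z["ratio_stabilizer"]),
                freq_axis_hz=fa if fa.size else None,
            )


def safe_elementwise_ratio(
    R: np.ndarray, X: np.ndarray, stabilizer: float
) -> np.ndarray:
    """Entrywise R / (X + stabilizer) with (R = 0, X = 0) entries set to 0.

    X holds non-negative magnitudes, so the additive stabilizer only guards
    near-zero entries.
    """
    R = np.asarray(R, dtype=float)
    X = np.asarray(X, dtype=float)
    if R.shape != X.shape:
        raise ValueError(f"R and X shapes differ: {R.shape} vs {X.shape}")
    if stabilizer <= 0:
        raise ValueError("stabilizer must be positive")
    ratio = R / (X + stabilizer)
    ratio[(R == 0) & (X == 0)] = 0.0
    return ratio


def default_stabilizer(X: np.ndarray) -> float:
    """1e-6 times the median nonzero input magnitude."""
    nz = np.asarray(X)[np.asarray(X) > 0]
    return 1e-6 * (np.median(nz) if nz.size else 1.0)


def compute_alw(
    relevances: np.ndarray,
    features: np.ndarray,
    tau: int,
    window: str,
    stabilizer: float | None = None,
    exclude_zero_zero: bool = True,
) -> np.ndarray:
    """One class's kernel slab (n, tau) from D samples' relevance and input.

    ``relevances`` and ``features`` have shape (D, T, n); ``window`` is
    ``"start"`` (t in [1, tau]) or ``"end"`` (t in [T - tau + 1, T]).
    ``exclude_zero_zero`` drops (R = 0, X = 0) entries from the per-position
    average instead of counting them as zeros.
    """
    R = np.atleast_3d(np.asarray(relevances, dtype=float))
    X = np.atleast_3d(np.asarray(features, dtype=float))
    if R.shape != X.shape:
        raise ValueError("relevances and features must have identical shapes")
    D, T, n = X.shape
    if D < 1:
        raise ValueError("need at least one sample")
    if T < tau:
        raise ValueError(f"samples have T={T} < tau={tau}")
    if window == "start":
        Rw, Xw = R[:, :tau], X[:, :tau]
    elif window == "end":
        Rw, Xw = R[:, T - tau :], X[:, T - tau :]
    else:
        raise ValueError("window must be 'start' or 'end'")
    s = default_stabilizer(X) if stabilizer is None else stabilizer
    ratio = safe_elementwise_ratio(Rw, Xw, s)
    if exclude_zero_zero:
        valid = ~((Rw == 0) & (Xw == 0))
        count = np.maximum(valid.sum(axis=0), 1)
        slab = ratio.sum(axis=0) / count
    else:
        slab = ratio.mean(axis=0)
    return slab.T  # (n, tau)


def build_kernel(
    relevances_per_class: list[np.ndarray],
    features: np.ndarray,
    tau: int = 20,
    classes: np.ndarray | None = None,
    stabilizer: float | None = None,
    freq_axis_hz: np.ndarray | None = None,
) -> ALWKernel:
    """Stack per-class start/end slabs into the (n, tau, C) kernels."""
    X = np.asarray(features, dtype=float)
    s = default_stabilizer(X) if stabilizer is None else stabilizer
    starts, ends, singles = [], [], []
    for Rc in relevances_per_class:
        starts.append(compute_alw(Rc, X, tau, "start", s))
        ends.append(compute_alw(Rc, X, tau, "end", s))
    W_start = np.stack(starts, axis=2)
    W_end = np.stack(ends, axis=2)
    C = W_start.shape[2]
    return ALWKernel(
        W_start=W_start,
        W_end=W_end,
        tau=tau,
        classes=np.arange(C) if classes is None else np.asarray(classes),
        D_used=X.shape[0],
        ratio_stabilizer=s,
        freq_axis_hz=freq_axis_hz,
        W_single=W_start.copy(),
    )


def alw_scores(kernel: ALWKernel, feature_tensor) -> np.ndarray:
    """Class scores S (length C) for one sample, or (D, C) for a batch.

    When T = tau the start and end windows coincide and every input entry
    is counted twice — the degenerate boundary is allowed and documented.
    """
    X = feature_tensor.X if isinstance(feature_tensor, FeatureTensor) else np.asarray(feature_tensor, dtype=float)
    single = X.ndim == 2
    X = X[None] if single else X
    D, T, n = X.shape
    if T < kernel.tau:
        raise ValueError(f"T={T} < tau={kernel.tau}")
    if n != kernel.n:
        raise ValueError(f"expected {kernel.n} features, got {n}")
    Xs = X[:, : kernel.tau]  # (D, tau, n)
    Xe = X[:, T - kernel.tau :]
    S = np.einsum("dtn,ntc->dc", Xs, kernel.W_start) + np.einsum(
        "dtn,ntc->dc", Xe, kernel.W_end
    )
    return S[0] if single else S


def predict_from_scores(kernel: ALWKernel, S: np.ndarray) -> np.ndarray:
    S = np.atleast_2d(S)
    return kernel.classes[S.argmax(axis=1)]  # argmax ties -> lowest index


class ALWClassifier(BaseEstimator, ClassifierMixin):
    """Standalone linear classifier built from a trained network's LRP.

    ``fit(X, y)`` computes, for every training sample, the relevance of
    each class (regardless of the sample's own label, which enters only
    through the trained network), builds the start/end kernels, and stores
    them; ``class_conditional=True`` restricts each class's average to the
    samples of that class instead. ``predict`` uses only the kernels.
    """

    def __init__(
        self,
        network: BiLSTMClassifier | None = None,
        tau: int = 20,
        epsilon: float = 0.001,
        delta: float = 0.0,
        seed_mode: str = "softmax",
        stabilizer: float | None = None,
        class_conditional: bool = False,
    ):
        self.network = network
        self.tau = tau
        self.epsilon = epsilon
        self.delta = delta
        self.seed_mode = seed_mode
        self.stabilizer = stabilizer
        self.class_conditional = class_conditional

    def fit(self, X, y=None):
        if self.network is None or not hasattr(self.network, "params_"):
            raise ValueError("ALWClassifier requires an already fitted network")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must have shape (D, T, n)")
        if X.shape[1] < self.tau:
            raise ValueError(f"sequences of length {X.shape[1]} < tau={self.tau}")
        cfg = lrp_mod.LRPConfig(delta=self.delta, epsilon=self.epsilon, seed=self.seed_mode)
        self.classes_ = self.network.classes_
        rel_per_class = [
            lrp_mod.relevance(self.network, X, c, cfg).R
            for c in range(self.classes_.size)
        ]
        if self.class_conditional:
            if y is None:
                raise ValueError("class_conditional averaging needs y")
            y = np.asarray(y)
            starts, ends = [], []
            s = default_stabilizer(X) if self.stabilizer is None else self.stabilizer
            for c in range(self.classes_.size):
                mask = y == self.classes_[c]
                starts.append(compute_alw(rel_per_class[c][mask], X[mask], self.tau, "start", s))
                ends.append(compute_alw(rel_per_class[c][mask], X[mask], self.tau, "end", s))
            self.kernel_ = ALWKernel(
                W_start=np.stack(starts, 2),
                W_end=np.stack(ends, 2),
                tau=self.tau,
                classes=self.classes_,
                D_used=X.shape[0],
                ratio_stabilizer=s,
            )
        else:
            self.kernel_ = build_kernel(
                rel_per_class, X, self.tau, self.classes_, self.stabilizer
            )
        return self

    def decision_function(self, X):
        check_is_fitted(self, "kernel_")
        return np.atleast_2d(alw_scores(self.kernel_, np.asarray(X, dtype=float)))

    def predict(self, X):
        return predict_from_scores(self.kernel_, self.decision_function(X))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def alw_fidelity(
    alw_classifier, network: BiLSTMClassifier, X_test, y_test
) -> dict:
    """Accuracy of both classifiers on a shared test set plus agreement rate."""
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise ValueError("empty test set")
    pred_alw = alw_classifier.predict(X_test)
    pred_nn = network.predict(X_test)
    return {
        "alw_accuracy": float(np.mean(pred_alw == y_test)),
        "nn_accuracy": float(np.mean(pred_nn == y_test)),
        "agreement_rate": float(np.mean(pred_alw == pred_nn)),
        "alw_metrics": metrics_from_predictions(y_test, pred_alw),
        "nn_metrics": metrics_from_predictions(y_test, pred_nn),
    }
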