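"""Layer-wise relevance propagation through the BiLSTM classifier.

The engine decomposes a class score into per-input relevance values by
walking the network backwards: fully connected layer -> (dropout, identity
at explanation time) -> batch normalization (folded into an equivalent
per-feature affine map) -> the two LSTM directions, unrolled over time.

Affine layers use the epsilon-stabilized rule

    R_i = sum_j (w_ij z_i + (delta b_j + eps sign(z_j)) / N_i)
                / (z_j + eps sign(z_j)) * R_j

with ``sign(0) := +1`` and ``N_i`` the layer fan-in. The LSTM uses the
signal-takes-all convention for recurrent networks: multiplicative gates
(input, forget, output sigmoids) receive zero relevance; cell relevance at
each step is split between the carried-over cell state ``f * c_prev`` and
the new candidate ``i * g`` with the same stabilized rule; candidate
relevance reaches the inputs and the previous hidden state through the
candidate's affine pre-activation.

Relevance is seeded at the target class's output: by default the softmax
probability of that class placed on its logit (the other logits get zero);
``seed="logit"`` seeds the raw logit instead, which makes the propagation
exactly conservative for bias-free linear networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import BiLSTMClassifier, forward
from .preprocess import FeatureTensor


@dataclass
class LRPConfig:
    delta: float = 0.0
    epsilon: float = 0.001
    seed: str = "softmax"  # or "logit"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.seed not in ("softmax", "logit"):
            raise ValueError("seed must be 'softmax' or 'logit'")


@dataclass
class RelevanceTensor:
    """Input-shaped relevance for one target class (batched: (D, T, n))."""

    R: np.ndarray
    target_class: int
    seeded_score: np.ndarray  # (D,)
    layer_sums: dict = field(default_factory=dict)


def _sign(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0, -1.0)


def lrp_linear(
    R_out: np.ndarray,
    z_in: np.ndarray,
    z_out: np.ndarray,
    W: np.ndarray,
    b: np.ndarray | None = None,
    delta: float = 0.0,
    epsilon: float = 0.001,
    fan_in: int | None = None,
) -> np.ndarray:
    """Epsilon-rule relevance through an affine layer ``z_out = z_in W + b``.

    All arrays may carry a leading batch axis. ``fan_in`` defaults to the
    number of input neurons.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError("W must be 2-D (fan_in x fan_out)")
    Ni = W.shape[0] if fan_in is None else fan_in
    b = np.zeros(W.shape[1]) if b is None else np.asarray(b, dtype=float)
    z_in = np.atleast_2d(np.asarray(z_in, dtype=float))
    z_out = np.atleast_2d(np.asarray(z_out, dtype=float))
    R_out = np.atleast_2d(np.asarray(R_out, dtype=float))
    if z_in.shape[1] != W.shape[0] or z_out.shape[1] != W.shape[1]:
        raise ValueError("activation shapes inconsistent with W")
    if R_out.shape != z_out.shape:
        raise ValueError("R_out must match z_out's shape")
    stab = epsilon * _sign(z_out)
    Rn = R_out / (z_out + stab)  # (B, Nj)
    # R_i = z_i * sum_j W_ij Rn_j  +  (1/N_i) sum_j (delta b_j + stab_j) Rn_j
    share = ((delta * b + stab) * Rn).sum(axis=1, keepdims=True) / Ni
    R_in = z_in * (Rn @ W.T) + share
    return R_in


def fold_batchnorm(gamma, beta, mean, var, eps_bn: float = 1e-5):
    """Equivalent per-feature affine (scale, shift) of a frozen BN layer."""
    var = np.asarray(var, dtype=float)
    if np.any(var <= 0):
        raise ValueError("BN running variance must be positive")
    inv_std = 1.0 / np.sqrt(var + eps_bn)
    return gamma * inv_std, beta - gamma * mean * inv_std


def lrp_batchnorm(
    R_out: np.ndarray,
    z_in: np.ndarray,
    gamma,
    beta,
    mean,
    var,
    eps_bn: float = 1e-5,
    config: LRPConfig | None = None,
) -> np.ndarray:
    """BN folded into a diagonal affine map; each feature is its own
    fan-in-1 linear layer under the epsilon rule."""
    cfg = config or LRPConfig()
    scale, shift = fold_batchnorm(gamma, beta, mean, var, eps_bn)
    z_in = np.atleast_2d(z_in)
    z_out = z_in * scale + shift
    R_out = np.atleast_2d(R_out)
    stab = cfg.epsilon * _sign(z_out)
    return (scale * z_in + cfg.delta * shift + stab) / (z_out + stab) * R_out


def lrp_lstm_cell(
    trace: dict,
    R_h_last: np.ndarray,
    Wx: np.ndarray,
    Wh: np.ndarray,
    b: np.ndarray,
    config: LRPConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Unroll one LSTM direction backwards under signal-takes-all.

    ``trace`` is the forward trace of that direction (hs, cs, gates, X, in
    that direction's time order). ``R_h_last`` (B, H) is the relevance
    arriving at the final hidden state. Returns ``(R_x, R_c0)``: input
    relevance (B, T, n) in the trace's time order, and the relevance left
    on the initial cell state (a leakage term, zero when c_0 = 0).
    """
    cfg = config or LRPConfig()
    X, hs, cs, gates = trace["X"], trace["hs"], trace["cs"], trace["gates"]
    B, T, n = X.shape
    H = R_h_last.shape[-1]
    Wg = Wx[:, 2 * H : 3 * H]
    Ug = Wh[:, 2 * H : 3 * H]
    bg = b[2 * H : 3 * H]
    W_cand = np.concatenate([Wg, Ug], axis=0)  # (n + H, H)

    R_x = np.zeros((B, T, n))
    Rc = R_h_last.astype(float).copy()  # h = o * tanh(c): all relevance to c
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H : 2 * H]
        g = gates[:, t, 2 * H : 3 * H]
        c_prev, c_t = cs[:, t], cs[:, t + 1]
        z_carry = f * c_prev
        z_cand = i * g
        stab = cfg.epsilon * _sign(c_t)
        denom = c_t + stab
        # two-way split of cell relevance (fan-in 2, unit weights, no bias)
        R_carry = (z_carry + stab / 2.0) / denom * Rc
        R_cand = (z_cand + stab / 2.0) / denom * Rc
        # candidate relevance through its affine pre-activation a_g;
        # the tanh and the input-gate product are pass-through (signal path)
        a_g = X[:, t] @ Wg + hs[:, t] @ Ug + bg
        z_in = np.concatenate([X[:, t], hs[:, t]], axis=1)
        R_xh = lrp_linear(
            R_cand, z_in, a_g, W_cand, bg, cfg.delta, cfg.epsilon
        )
        R_x[:, t] = R_xh[:, :n]
        if t > 0:
            # h_{t-1} = o_{t-1} * tanh(c_{t-1}): its relevance joins the cell chain
            Rc = R_carry + R_xh[:, n:]
        else:
            # initial hidden state is zero; relevance remaining on the
            # zero-valued carry is reported as leakage
            Rc = R_carry
    return R_x, Rc


def lrp_bilstm(
    params: dict,
    cache: dict,
    R_summary: np.ndarray,
    hidden_units: int,
    config: LRPConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Split summary relevance into the two directions and unroll each.

    The first half of the summary is the forward direction's final hidden
    state (sequence end); the second half is the backward direction's final
    state (sequence start). Input relevance is their sum per (t, feature).
    """
    cfg = config or LRPConfig()
    H = hidden_units
    R_f = R_summary[:, :H]
    R_b = R_summary[:, H:]
    Rx_f, Rc0_f = lrp_lstm_cell(
        cache["trace_f"], R_f, params["Wx_f"], params["Wh_f"], params["b_f"], cfg
    )
    Rx_b, Rc0_b = lrp_lstm_cell(
        cache["trace_b"], R_b, params["Wx_b"], params["Wh_b"], params["b_b"], cfg
    )
    R = Rx_f + Rx_b[:, ::-1]  # backward trace runs on the reversed sequence
    audit = {"initial_cell_fwd": Rc0_f.sum(), "initial_cell_bwd": Rc0_b.sum()}
    return R, audit


def relevance(
    network: BiLSTMClassifier,
    feature_tensor,
    target_class: int,
    config: LRPConfig | None = None,
) -> RelevanceTensor:
    """Input-shaped relevance of one target class for one or many samples.

    ``feature_tensor`` may be a :class:`FeatureTensor`, a (T, n) array, or
    a batched (D, T, n) array. ``target_class`` indexes
    ``network.classes_``. Dropout is identity at explanation time; BN uses
    its frozen running moments.
    """
    cfg = config or LRPConfig()
    X = feature_tensor.X if isinstance(feature_tensor, FeatureTensor) else np.asarray(feature_tensor)
    single = X.ndim == 2
    X = network._validate_X(X)
    ncfg = network.config_
    if not 0 <= target_class < ncfg.n_classes:
        raise ValueError(f"target_class must be in [0, {ncfg.n_classes})")
    cache = forward(
        network.params_, X, ncfg, train=False, bn_state=network.bn_state_
    )
    logits, probs = cache["logits"], cache["probs"]
    seeded = probs[:, target_class] if cfg.seed == "softmax" else logits[:, target_class]
    R_logits = np.zeros_like(logits)
    R_logits[:, target_class] = seeded

    layer_sums = {"seeded": seeded.sum()}
    R_bn_out = lrp_linear(
        R_logits,
        cache["do_out"],
        logits,
        network.params_["fc_W"],
        network.params_["fc_b"],
        cfg.delta,
        cfg.epsilon,
    )
    layer_sums["after_fc"] = R_bn_out.sum()
    if ncfg.bn_enabled:
        R_summary = lrp_batchnorm(
            R_bn_out,
            cache["summary"],
            network.params_["bn_gamma"],
            network.params_["bn_beta"],
            network.bn_state_["mean"],
            network.bn_state_["var"],
            ncfg.bn_eps,
            cfg,
        )
    else:
        R_summary = R_bn_out
    layer_sums["after_bn"] = R_summary.sum()
    R, audit = lrp_bilstm(network.params_, cache, R_summary, ncfg.hidden_units, cfg)
    layer_sums["input_total"] = R.sum()
    layer_sums.update(audit)
    return RelevanceTensor(
        R=R[0] if single else R,
        target_class=target_class,
        seeded_score=seeded,
        layer_sums=layer_sums,
    )


def relevance_all_classes(
    network: BiLSTMClassifier, X: np.ndarray, config: LRPConfig | None = None
) -> list[RelevanceTensor]:
    """One batched RelevanceTensor per class, in ``network.classes_`` order."""
    return [
        relevance(network, X, c, config) for c in range(network.config_.n_classes)
    ]


def conservation_report(rt: RelevanceTensor) -> pd.DataFrame:
    """Per-layer relevance sums and leakage relative to the seeded score.

    Leakage (the difference between a layer's total relevance and the
    seeded score) is attributable to the epsilon stabilizers, the bias
    terms, and the gate/initial-state cut-offs of the LSTM rule.
    """
    seeded = rt.layer_sums["seeded"]
    rows = []
    for layer in ("seeded", "after_fc", "after_bn", "input_total"):
        if layer in rt.layer_sums:
            s = rt.layer_sums[layer]
            rows.append({"layer": layer, "relevance_sum": s, "leakage": s - seeded})
    return pd.DataFrame(rows)
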