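"""Validation and interpretation analyses for the explained classifier.

* Erasure analysis — faithfulness check: zero input entries ranked by
  relevance (most-positive first, most-negative first, or random) and
  watch the accuracy respond. Removing positive-relevance entries should
  collapse accuracy; removing negative-relevance entries should raise it;
  at fraction 1 all strategies coincide (the input is all zeros).
* Timestep preservation — zero everything except the first and last k
  timesteps; the accuracy curve plateaus once k covers the
  relevance-carrying sequence edges.
* Quartered signs — the 4-letter P/N code of a kernel weight sequence:
  sign before/after the first flip in the start window, then in the end
  window.
* Summed weights and the High/Low feature table — per (site, frequency,
  class) totals of the linear kernel, normalized across classes, labelled
  High (positive correlation with the class score) or Low, with a
  uniqueness marker when one class's label differs from both others.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import lrp as lrp_mod
from .alw import ALWKernel
from .synthetic import PART_NAMES

ERASURE_STRATEGIES = ("positive", "negative", "random")


def _predicted_class_relevance(network, X, lrp_config):
    """Relevance of each sample's *predicted* class, stacked (D, T, n)."""
    preds = network.predict_proba(X).argmax(axis=1)
    rel = np.empty_like(np.asarray(X, dtype=float))
    for c in np.unique(preds):
        mask = preds == c
        rel[mask] = lrp_mod.relevance(network, np.asarray(X)[mask], int(c), lrp_config).R
    return rel


def erase_by_relevance(
    X: np.ndarray,
    relevance: np.ndarray,
    strategy: str,
    fraction: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero the top-``fraction`` of entries of each sample by the strategy's
    ranking: ``positive`` zeroes the largest relevance first, ``negative``
    the smallest (most negative) first, ``random`` a seeded random subset."""
    if strategy not in ERASURE_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected {ERASURE_STRATEGIES}")
    X = np.asarray(X, dtype=float).copy()
    D = X.shape[0]
    n_entries = X[0].size
    k = int(round(fraction * n_entries))
    if k == 0:
        return X
    flatX = X.reshape(D, -1)
    flatR = np.asarray(relevance).reshape(D, -1)
    for d in range(D):
        if strategy == "positive":
            order = np.argsort(-flatR[d])
        elif strategy == "negative":
            order = np.argsort(flatR[d])
        else:
            order = rng.permutation(n_entries)
        flatX[d, order[:k]] = 0.0
    return flatX.reshape(X.shape)


def erasure_analysis(
    network,
    X_test,
    y_test,
    fractions,
    strategies=ERASURE_STRATEGIES,
    lrp_config: lrp_mod.LRPConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy after zeroing ranked input entries, per strategy/fraction.

    Entries are ranked by each sample's predicted-class relevance at
    individual (timestep, feature) granularity; the ranking is computed
    once on the intact inputs.
    """
    cfg = lrp_config or lrp_mod.LRPConfig()
    for s in strategies:
        if s not in ERASURE_STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}; expected {ERASURE_STRATEGIES}")
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    rel = _predicted_class_relevance(network, X_test, cfg)
    rows = []
    for strategy in strategies:
        rng = np.random.default_rng(seed)
        for f in fractions:
            Xz = erase_by_relevance(X_test, rel, strategy, f, rng)
            acc = float(np.mean(network.predict(Xz) == y_test))
            rows.append({"strategy": strategy, "fraction": f, "accuracy": acc})
    return pd.DataFrame(rows)


def erase_negative_relevance(network, X_test, y_test, lrp_config=None) -> float:
    """Accuracy after zeroing *every* negative-relevance input entry."""
    cfg = lrp_config or lrp_mod.LRPConfig()
    X_test = np.asarray(X_test, dtype=float)
    rel = _predicted_class_relevance(network, X_test, cfg)
    Xz = np.where(rel < 0, 0.0, X_test)
    return float(np.mean(network.predict(Xz) == np.asarray(y_test)))


def preserve_edges(X: np.ndarray, k: int) -> np.ndarray:
    """Zero all timesteps except the first and last ``k``."""
    X = np.asarray(X, dtype=float)
    T = X.shape[-2]
    if k > T // 2:
        raise ValueError(f"k={k} exceeds T/2={T // 2}")
    out = np.zeros_like(X)
    if k > 0:
        out[..., :k, :] = X[..., :k, :]
        out[..., T - k :, :] = X[..., T - k :, :]
    return out


def timestep_preservation_curve(network, X_test, y_test, k_values) -> pd.DataFrame:
    """Accuracy vs number of preserved start/end timesteps."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    rows = []
    for k in k_values:
        Xk = preserve_edges(X_test, int(k))
        rows.append(
            {"k": int(k), "accuracy": float(np.mean(network.predict(Xk) == y_test))}
        )
    return pd.DataFrame(rows)


def plateau_detect(curve: pd.DataFrame, tolerance: float = 0.02):
    """Smallest k whose accuracy is within ``tolerance`` of the accuracy at
    the largest (full-preservation) k; ``None`` when no k qualifies."""
    curve = curve.sort_values("k")
    full = curve["accuracy"].iloc[-1]
    hits = curve[curve["accuracy"] >= full - tolerance]
    return int(hits["k"].iloc[0]) if len(hits) else None


def relevance_heatmap(R: np.ndarray, freq_axis_hz, path=None, n_edge: int = 20):
    """Heatmap of one sample's relevance: x = timestep, y = the 105 features
    stacked L/H/U with frequencies ascending top-down within each site.

    Only the first and last ``n_edge`` timesteps are drawn (the middle
    carries near-zero relevance). Returns the matplotlib figure; saves to
    ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    R = np.asarray(R)
    T, n = R.shape
    nb = len(freq_axis_hz)
    # ascending top-down: flip each site block vertically
    blocks = [R[:, p * nb : (p + 1) * nb].T[::-1] for p in range(len(PART_NAMES))]
    img = np.concatenate(blocks, axis=0)
    shown = np.concatenate([img[:, :n_edge], img[:, T - n_edge :]], axis=1)
    vmax = np.abs(shown).max() or 1.0
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(shown, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.axvline(n_edge - 0.5, color="k", lw=0.8)
    for p in range(1, len(PART_NAMES)):
        ax.axhline(p * nb - 0.5, color="k", lw=0.8)
    ax.set_yticks([nb // 2 + p * nb for p in range(len(PART_NAMES))])
    ax.set_yticklabels(PART_NAMES)
    ax.set_xlabel(f"first {n_edge} | last {n_edge} timesteps")
    fig.colorbar(im, ax=ax, label="relevance")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def _window_signs(weights: np.ndarray) -> tuple[str, str]:
    """(pre-flip, post-flip) signs of one window's weight sequence.

    Zero weights inherit the previous nonzero sign; with no sign flip the
    second symbol copies the first; an all-zero sequence is undefined (U).
    """
    w = np.asarray(weights, dtype=float)
    nz = w != 0
    if not nz.any():
        return "U", "U"
    signs = np.where(w > 0, 1, np.where(w < 0, -1, 0))
    # forward-fill zeros with the previous nonzero sign; leading zeros take
    # the first nonzero sign
    first = signs[nz][0]
    filled = np.empty_like(signs)
    cur = first
    for i, s in enumerate(signs):
        if s != 0:
            cur = s
        filled[i] = cur
    flips = np.nonzero(np.diff(filled) != 0)[0]
    pre = "P" if filled[0] > 0 else "N"
    if flips.size == 0:
        return pre, pre
    # only the first flip defines the quarter boundary; later flips ignored
    post = "P" if filled[flips[0] + 1] > 0 else "N"
    return pre, post


def quarter_signs(kernel: ALWKernel, feature_index: int, class_index: int) -> str:
    """4-letter P/N code for one (feature, class): start window pre/post
    first sign flip, then end window pre/post first sign flip."""
    if kernel.tau < 2:
        raise ValueError("quartering needs tau >= 2")
    q1, q2 = _window_signs(kernel.W_start[feature_index, :, class_index])
    q3, q4 = _window_signs(kernel.W_end[feature_index, :, class_index])
    return q1 + q2 + q3 + q4


def sign_table(kernel: ALWKernel, class_names=None) -> pd.DataFrame:
    """Quartered-sign strings for every (site, frequency, class)."""
    names = _class_names(kernel, class_names)
    freq = _freq_axis(kernel)
    nb = len(freq)
    rows = []
    for fi in range(kernel.n):
        part = PART_NAMES[fi // nb]
        f_hz = freq[fi % nb]
        row = {"part": part, "freq_hz": round(float(f_hz), 1)}
        for ci, cname in enumerate(names):
            row[cname] = quarter_signs(kernel, fi, ci)
        rows.append(row)
    return pd.DataFrame(rows)


def _class_names(kernel, class_names):
    if class_names is not None:
        return list(class_names)
    return [str(c) for c in kernel.classes]


def _freq_axis(kernel):
    if kernel.freq_axis_hz is not None:
        return np.asarray(kernel.freq_axis_hz)
    n = kernel.n
    if n >= len(PART_NAMES) and n % len(PART_NAMES) == 0:
        return np.arange(n // len(PART_NAMES), dtype=float)
    return np.arange(n, dtype=float)  # no site structure: single block


def summed_weights(kernel: ALWKernel, class_names=None) -> pd.DataFrame:
    """Per (site, frequency, class): kernel weights summed over both
    windows' timesteps, plus the value normalized to [-1, 1] across classes
    (division by the max absolute sum for that feature; all-zero features
    normalize to zero)."""
    names = _class_names(kernel, class_names)
    freq = _freq_axis(kernel)
    nb = len(freq)
    sums = kernel.W_start.sum(axis=1) + kernel.W_end.sum(axis=1)  # (n, C)
    scale = np.abs(sums).max(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    normalized = sums / scale
    rows = []
    for fi in range(kernel.n):
        for ci, cname in enumerate(names):
            rows.append(
                {
                    "part": PART_NAMES[fi // nb],
                    "freq_hz": round(float(freq[fi % nb]), 1),
                    "feature_index": fi,
                    "class": cname,
                    "summed_weight": float(sums[fi, ci]),
                    "normalized_weight": float(normalized[fi, ci]),
                }
            )
    return pd.DataFrame(rows)


def feature_table(summary: pd.DataFrame) -> pd.DataFrame:
    """High/Low label per (site, frequency) x class with uniqueness flags.

    High means the summed weight is positive — the frequency's magnitude
    correlates positively with the class score, i.e. that class carries
    relatively more of that frequency at that site. A label gets ``*`` when
    it differs from both other classes' labels. Depends only on the signs
    of the summed weights.
    """
    classes = list(dict.fromkeys(summary["class"]))
    pivot = summary.pivot_table(
        index=["part", "freq_hz", "feature_index"],
        columns="class",
        values="summed_weight",
        sort=False,
    )[classes]
    out_rows = []
    for (part, f_hz, fi), row in pivot.iterrows():
        labels = {c: ("High" if row[c] > 0 else "Low") for c in classes}
        cells = {}
        for c in classes:
            others = [labels[o] for o in classes if o != c]
            unique = all(labels[c] != o for o in others)
            cells[c] = labels[c] + ("*" if unique else "")
        out_rows.append({"part": part, "freq_hz": f_hz, **cells})
    return pd.DataFrame(out_rows)
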