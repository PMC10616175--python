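"""Run configuration and the end-to-end pipeline.

A single YAML document with per-stage sections drives the whole chain
(simulate -> preprocess -> train -> lrp -> alw -> interpret). Every
method constant — LRP epsilon = 0.001 and delta = 0.0, tau = 20, dropout
0.4, the 80:20 train/validation split, the class-balanced test set of 30,
the 3–30 Hz band — lives here as a default rather than being hard-coded
in the stages, and every stochastic stage has its own explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import alw as alw_mod
from . import interpret as interp_mod
from . import lrp as lrp_mod
from . import network as net_mod
from . import preprocess as pp_mod
from . import synthetic as syn_mod


@dataclass
class Seeds:
    cohort: int = 42
    split: int = 1
    oversample: int = 2
    training: int = 3
    erasure: int = 4


@dataclass
class RunConfig:
    seeds: Seeds = field(default_factory=Seeds)
    cohort: syn_mod.CohortConfig = field(default_factory=syn_mod.CohortConfig)
    preprocess: pp_mod.PreprocessConfig = field(default_factory=pp_mod.PreprocessConfig)
    # network
    hidden_units: int = 64
    dropout_p: float = 0.4
    input_dropout_p: float = 0.1
    bn_enabled: bool = True
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 120
    patience: int = 20
    test_per_class: int = 10
    val_fraction: float = 0.2
    # lrp
    lrp: lrp_mod.LRPConfig = field(default_factory=lrp_mod.LRPConfig)
    # alw
    tau: int = 20
    ratio_stabilizer: float | None = None
    # interpret
    erasure_fractions: tuple = (0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0)
    preserve_k_values: tuple = (0, 5, 10, 15, 20, 30, 40)
    plateau_tolerance: float = 0.02

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "seeds" in d:
            d["seeds"] = Seeds(**d["seeds"])
        if "cohort" in d:
            c = dict(d["cohort"])
            for k in ("duration_range_s", "pd_center_range_hz", "et_center_range_hz"):
                if k in c:
                    c[k] = tuple(c[k])
            d["cohort"] = syn_mod.CohortConfig(**c)
        if "preprocess" in d:
            d["preprocess"] = pp_mod.PreprocessConfig(**d["preprocess"])
        if "lrp" in d:
            d["lrp"] = lrp_mod.LRPConfig(**d["lrp"])
        for k in ("erasure_fractions", "preserve_k_values"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and persist each stage's outputs plus a manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    cfg.to_yaml(out / "config.yaml")

    # simulate + preprocess
    cohort = syn_mod.generate_cohort(cfg.cohort, cfg.seeds.cohort)
    feats = pp_mod.featurize_cohort(cohort, cfg.preprocess)
    pp_mod.save_features(out / "features.npz", feats)
    X, y = pp_mod.stack_features(feats)
    if X.shape[1] < cfg.tau:
        raise ValueError(
            f"trimmed sequence length {X.shape[1]} is below tau={cfg.tau}; "
            "lengthen recordings or reduce the hop"
        )

    # split + train
    split = net_mod.split_dataset(y, cfg.seeds.split, cfg.test_per_class)
    train_ids = net_mod.oversample_minority(
        split.train_ids, y, cfg.seeds.oversample, forbidden=split.test_ids
    )
    clf = net_mod.BiLSTMClassifier(
        hidden_units=cfg.hidden_units,
        dropout_p=cfg.dropout_p,
        input_dropout_p=cfg.input_dropout_p,
        bn_enabled=cfg.bn_enabled,
        lr=cfg.lr,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        random_state=cfg.seeds.training,
    )
    clf.fit(X[train_ids], y[train_ids], X_val=X[split.val_ids], y_val=y[split.val_ids])
    np.savez(out / "model.npz", **clf.params_, bn_mean=clf.bn_state_["mean"], bn_var=clf.bn_state_["var"])
    nn_metrics = net_mod.evaluate(clf, X[split.test_ids], y[split.test_ids])

    # lrp on the test set (per class) + conservation audit
    rels = lrp_mod.relevance_all_classes(clf, X[split.test_ids], cfg.lrp)
    np.savez(
        out / "relevance.npz",
        **{f"R_class_{c}": rt.R for c, rt in enumerate(rels)},
        seeded=np.stack([rt.seeded_score for rt in rels]),
    )
    audit = lrp_mod.conservation_report(rels[0])
    audit.to_csv(out / "conservation.csv", index=False)

    # alw from the (oversampled, class-balanced) training split only
    alw_clf = alw_mod.ALWClassifier(
        network=clf,
        tau=cfg.tau,
        epsilon=cfg.lrp.epsilon,
        delta=cfg.lrp.delta,
        seed_mode=cfg.lrp.seed,
        stabilizer=cfg.ratio_stabilizer,
    ).fit(X[train_ids], y[train_ids])
    alw_clf.kernel_.freq_axis_hz = feats[0].freq_axis_hz
    alw_clf.kernel_.save(out / "alw.npz")
    fidelity = alw_mod.alw_fidelity(alw_clf, clf, X[split.test_ids], y[split.test_ids])

    # interpret
    erasure = interp_mod.erasure_analysis(
        clf, X[split.test_ids], y[split.test_ids],
        cfg.erasure_fractions, lrp_config=cfg.lrp, seed=cfg.seeds.erasure,
    )
    erasure.to_csv(out / "erasure.csv", index=False)
    k_values = [k for k in cfg.preserve_k_values if k <= X.shape[1] // 2]
    preserve = interp_mod.timestep_preservation_curve(
        clf, X[split.test_ids], y[split.test_ids], k_values
    )
    preserve.to_csv(out / "preserve.csv", index=False)
    summary = interp_mod.summed_weights(alw_clf.kernel_, class_names=list(clf.classes_))
    summary.to_csv(out / "summed_weights.csv", index=False)
    interp_mod.feature_table(summary).to_csv(out / "feature_table.csv", index=False)
    interp_mod.sign_table(alw_clf.kernel_, class_names=list(clf.classes_)).to_csv(
        out / "sign_table.csv", index=False
    )

    def _strip(m):
        return {
            "accuracy": m["accuracy"],
            "per_class": m["per_class"],
        }

    manifest = {
        "stages": [
            "simulate", "preprocess", "train", "lrp", "alw", "interpret",
        ],
        "seeds": asdict(cfg.seeds),
        "n_recordings": len(cohort),
        "sequence_length": int(X.shape[1]),
        "n_features": int(X.shape[2]),
        "epochs_trained": clf.n_epochs_,
        "nn_metrics": _strip(nn_metrics),
        "alw_accuracy": fidelity["alw_accuracy"],
        "nn_accuracy": fidelity["nn_accuracy"],
        "agreement_rate": fidelity["agreement_rate"],
        "plateau_k": interp_mod.plateau_detect(preserve, cfg.plateau_tolerance),
        "outputs": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
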