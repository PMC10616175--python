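"""Synthetic upper-limb tremor cohort generator.

Emulates triaxial-site tremor recordings (lower arm L, hand H, upper arm U,
one scalar tremor-magnitude channel per site) for three subject groups:

* ``N``  — normal subjects: a ~3.1 Hz voluntary drinking component plus a
  weak, broadband 20–30 Hz physiological tremor; no dominant component in
  the 4–12 Hz pathological band.
* ``PD`` — Parkinson's disease: a dominant narrowband component in 4–6 Hz.
* ``ET`` — essential tremor: a dominant narrowband component in 4–12 Hz
  (default template centred in 7–10 Hz so the PD and ET bands are
  distinguishable at cohort scale).

Recordings have jittered (non-uniform) timestamps and subject-varying
durations so the downstream shape-preserving resampling and
trim-to-common-length stages are exercised. The drinking action carries a
slow amplitude envelope — movement phases at the start (reach/lift) and end
(put down) of the action are stronger than the middle hold — so the edges
of a sequence carry class information the way an action-tremor recording
does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CLASS_LABELS = ("N", "PD", "ET")
ACTIONS = ("DRINK", "FNF", "OUT", "REST", "WING", "EAT")
PART_NAMES = ("L", "H", "U")

#: pathological band limits (Hz) reported for each tremor class
PD_BAND = (4.0, 6.0)
ET_BAND = (4.0, 12.0)


@dataclass
class SubjectProfile:
    """Spectral template of one synthetic subject."""

    class_label: str
    #: list of (center_freq_hz, amplitude, bandwidth_hz, phase) tremor components
    tremor_components: list[tuple[float, float, float, float]]
    #: (freq_hz, amplitude) voluntary movement component (~3.1 Hz for drinking)
    voluntary_component: tuple[float, float]
    #: (low_hz, high_hz, amplitude) broadband physiological tremor band
    physiological_band: tuple[float, float, float]
    #: relative gain per measurement site, ordered (L, H, U)
    per_part_gain: tuple[float, float, float]
    duration_s: float = 12.0
    reaction_delay_s: float = 0.0
    noise_sd: float = 0.1

    def validate(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"unknown class label {self.class_label!r}; expected one of {CLASS_LABELS}"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.reaction_delay_s < 0:
            raise ValueError("reaction_delay_s must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for f, a, bw, _ in self.tremor_components:
            if a < 0 or bw < 0 or f <= 0:
                raise ValueError("tremor components need f > 0, amplitude >= 0, bandwidth >= 0")
        if any(a < 0 for a in (self.voluntary_component[1], self.physiological_band[2])):
            raise ValueError("amplitudes must be non-negative")


@dataclass
class TremorRecording:
    """One multi-site recording: rows of ``signal`` are ordered L, H, U."""

    timestamps_s: np.ndarray
    signal: np.ndarray
    class_label: str
    action: str
    subject_id: str

    def validate(self) -> None:
        if self.timestamps_s.ndim != 1 or np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.signal.shape != (3, self.timestamps_s.size):
            raise ValueError("signal must be 3 x len(timestamps), rows ordered L, H, U")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")


@dataclass
class CohortConfig:
    """Cohort composition and amplitude conditions.

    Default class counts keep the clinical imbalance (normal > Parkinson's
    >> essential tremor) at desk scale; essential tremor stays the minority
    class, which is what the oversampling stage downstream compensates.
    """

    n_per_class: dict = field(default_factory=lambda: {"N": 50, "PD": 45, "ET": 15})
    action: str = "DRINK"
    #: spread kept below the movement-phase length so that trimming every
    #: sequence to the shortest still leaves part of the put-down movement
    #: inside the trailing window of every subject
    duration_range_s: tuple[float, float] = (25.0, 26.0)
    fs_nominal_hz: float = 200.0
    timestamp_jitter: float = 0.25  # fraction of the nominal timestep
    noise_sd: float = 0.05
    # class spectral templates: amplitudes of tremor / voluntary / physiological parts
    pd_center_range_hz: tuple[float, float] = (4.6, 5.6)
    et_center_range_hz: tuple[float, float] = (7.0, 10.0)
    pd_amplitude: float = 1.8
    et_amplitude: float = 1.6
    voluntary_amp_normal: float = 1.0
    voluntary_amp_patient: float = 0.5
    physio_amp_normal: float = 0.30
    physio_amp_patient: float = 0.06


def sample_profile(
    class_label: str, rng_seed, config: CohortConfig | None = None
) -> SubjectProfile:
    """Draw a subject spectral profile for one class (deterministic per seed)."""
    if class_label not in CLASS_LABELS:
        raise ValueError(
            f"unknown class label {class_label!r}; expected one of {CLASS_LABELS}"
        )
    cfg = config or CohortConfig()
    rng = np.random.default_rng(rng_seed)
    dur = rng.uniform(*cfg.duration_range_s)
    delay = rng.uniform(0.0, 0.3)
    gains = (
        0.9 * rng.uniform(0.9, 1.1),
        1.1 * rng.uniform(0.9, 1.1),
        0.7 * rng.uniform(0.9, 1.1),
    )
    components: list[tuple[float, float, float, float]] = []
    if class_label == "PD":
        f0 = rng.uniform(*cfg.pd_center_range_hz)
        components.append((f0, cfg.pd_amplitude * rng.uniform(0.5, 1.2), 0.25, rng.uniform(0, 2 * np.pi)))
        voluntary = (3.1, cfg.voluntary_amp_patient * rng.uniform(0.8, 1.2))
        physio = (20.0, 30.0, cfg.physio_amp_patient * rng.uniform(0.8, 1.2))
    elif class_label == "ET":
        f0 = rng.uniform(*cfg.et_center_range_hz)
        components.append((f0, cfg.et_amplitude * rng.uniform(0.5, 1.2), 0.5, rng.uniform(0, 2 * np.pi)))
        voluntary = (3.1, cfg.voluntary_amp_patient * rng.uniform(0.8, 1.2))
        physio = (20.0, 30.0, 1.3 * cfg.physio_amp_patient * rng.uniform(0.8, 1.2))
    else:  # N
        voluntary = (3.1, cfg.voluntary_amp_normal * rng.uniform(0.8, 1.2))
        physio = (20.0, 30.0, cfg.physio_amp_normal * rng.uniform(0.8, 1.2))
    profile = SubjectProfile(
        class_label=class_label,
        tremor_components=components,
        voluntary_component=voluntary,
        physiological_band=physio,
        per_part_gain=gains,
        duration_s=dur,
        reaction_delay_s=delay,
        noise_sd=cfg.noise_sd,
    )
    profile.validate()
    return profile


def _drink_envelope(t: np.ndarray, duration: float, delay: float) -> np.ndarray:
    """Amplitude envelope of the drinking action.

    Movement phases (reach/lift at the start, put-down at the end) have full
    amplitude; the middle hold is attenuated. Transitions are raised-cosine.
    """
    move = min(2.0, 0.3 * duration)
    ramp = min(1.0, 0.5 * move)
    hold_level = 0.05

    def edge(x):  # smooth 0 -> 1 over [0, ramp]
        x = np.clip(x / ramp, 0.0, 1.0)
        return 0.5 - 0.5 * np.cos(np.pi * x)

    start_hi = 1.0 - (1.0 - hold_level) * edge(t - (delay + move))
    end_hi = hold_level + (1.0 - hold_level) * edge(t - (duration - move))
    env = np.maximum(start_hi, end_hi)
    # attack: nothing before the reaction delay
    env = env * edge(t - delay + ramp * 1e-9) if delay > 0 else env
    return env


def _narrowband(t: np.ndarray, f0: float, bw: float, phase: float, rng) -> np.ndarray:
    """Unit-amplitude narrowband oscillation centred at f0 with ~bw spread."""
    if bw <= 0:
        return np.sin(2 * np.pi * f0 * t + phase)
    n_tones = 9
    freqs = f0 + bw * rng.standard_normal(n_tones) / 2.355  # FWHM -> sd
    freqs = np.clip(freqs, 0.1, None)
    phases = rng.uniform(0, 2 * np.pi, n_tones)
    tones = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    out = tones.mean(axis=0)
    rms = max(np.sqrt(np.mean(out**2)), 1e-12)
    return out / (rms * np.sqrt(2.0))  # same RMS as a unit-amplitude sinusoid


def _bandnoise(t: np.ndarray, lo: float, hi: float, rng) -> np.ndarray:
    """Broadband unit-RMS noise from random tones spread over [lo, hi] Hz."""
    n_tones = 24
    freqs = rng.uniform(lo, hi, n_tones)
    phases = rng.uniform(0, 2 * np.pi, n_tones)
    tones = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    return tones.sum(axis=0) * np.sqrt(2.0 / n_tones)


def synthesize_recording(
    profile: SubjectProfile,
    action: str = "DRINK",
    rng_seed=0,
    fs_nominal_hz: float = 200.0,
    timestamp_jitter: float = 0.25,
) -> TremorRecording:
    """Render one recording from a profile (deterministic per seed).

    The signal per site is the gain-scaled sum of the narrowband tremor
    components, the low-frequency voluntary component, the broadband
    physiological band, and white noise. Timestamps carry sub-sample jitter
    so the series is non-uniform.
    """
    profile.validate()
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}; expected one of {ACTIONS}")
    if profile.duration_s < 2.0:
        raise ValueError("duration must be at least 2 s")
    rng = np.random.default_rng(rng_seed)
    dt = 1.0 / fs_nominal_hz
    n = int(round(profile.duration_s * fs_nominal_hz))
    jitter = timestamp_jitter * dt * rng.uniform(-0.49, 0.49, n)
    t = np.arange(n) * dt + jitter
    t[0] = 0.0
    t = np.maximum.accumulate(t + np.arange(n) * 1e-12)  # strictly increasing

    env = (
        _drink_envelope(t, profile.duration_s, profile.reaction_delay_s)
        if action == "DRINK"
        else np.ones_like(t)
    )
    base = np.zeros_like(t)
    for f0, amp, bw, phase in profile.tremor_components:
        base += amp * _narrowband(t, f0, bw, phase, rng)
    fv, av = profile.voluntary_component
    base_voluntary = av * np.sin(2 * np.pi * fv * t + rng.uniform(0, 2 * np.pi))
    lo, hi, ap = profile.physiological_band
    tremor = (base + base_voluntary) * env

    signal = np.empty((3, n))
    for p, gain in enumerate(profile.per_part_gain):
        # physiological tremor is transmitted through the moving limb, so it
        # follows the same movement envelope as the pathological components
        physio = ap * _bandnoise(t, lo, hi, rng) * env
        white = profile.noise_sd * rng.standard_normal(n)
        signal[p] = gain * (tremor + physio) + white

    rec = TremorRecording(
        timestamps_s=t,
        signal=signal,
        class_label=profile.class_label,
        action=action,
        subject_id="",
    )
    rec.validate()
    return rec


def generate_cohort(
    config: CohortConfig | None = None, master_seed: int = 0
) -> list[TremorRecording]:
    """Generate a labelled cohort; identical master seeds give identical cohorts."""
    cfg = config or CohortConfig()
    counts = dict(cfg.n_per_class)
    unknown = set(counts) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown class labels in cohort config: {sorted(unknown)}")
    if any(c < 1 for c in counts.values()) or sum(counts.values()) == 0:
        raise ValueError("per-class counts must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    recordings: list[TremorRecording] = []
    idx = 0
    for label in CLASS_LABELS:
        for k in range(counts.get(label, 0)):
            child = ss.spawn(1)[0]
            seeds = child.generate_state(2) % (2**31)
            prof = sample_profile(label, int(seeds[0]), cfg)
            prof = replace(prof, noise_sd=cfg.noise_sd)
            rec = synthesize_recording(
                prof,
                cfg.action,
                int(seeds[1]),
                fs_nominal_hz=cfg.fs_nominal_hz,
                timestamp_jitter=cfg.timestamp_jitter,
            )
            rec.subject_id = f"{label}{k:03d}"
            recordings.append(rec)
            idx += 1
    return recordings


def planted_truth(
    freq_axis_hz: np.ndarray, config: CohortConfig | None = None
) -> list[tuple[str, tuple[int, ...], str]]:
    """Generator-truth discriminative features: (part, bin indices, class).

    Each entry names one planted spectral feature whose cohort-mean
    magnitude is, by construction of the class templates, highest for the
    named class at every measurement site. A feature covers the bins its
    planted component actually spans: the Parkinson-band component for PD,
    the essential-tremor-band component for ET, and — for N — the voluntary
    3.1 Hz tone plus the broadband 20–30 Hz physiological band (one feature,
    since the band is planted as a whole, not bin by bin). Recovery of a
    feature is judged on the kernel weight summed over its bins.
    """
    cfg = config or CohortConfig()
    features: list[tuple[str, tuple[int, ...], str]] = []
    freq = np.asarray(freq_axis_hz)

    def bins_in(lo, hi):
        return tuple(int(b) for b in np.nonzero((freq >= lo) & (freq <= hi))[0])

    pd_bins = bins_in(cfg.pd_center_range_hz[0] + 0.1, cfg.pd_center_range_hz[1] - 0.1)
    et_lo, et_hi = cfg.et_center_range_hz
    et_bins = bins_in(et_lo + 0.8, et_hi - 0.8)
    vol_bin = (int(np.argmin(np.abs(freq - 3.1))),)
    physio_bins = bins_in(21.0, 29.0)
    for part in PART_NAMES:
        features.append((part, pd_bins, "PD"))
        features.append((part, et_bins, "ET"))
        features.append((part, vol_bin, "N"))
        features.append((part, physio_bins, "N"))
    return features


def planted_recovery(summary, freq_axis_hz, config: CohortConfig | None = None) -> float:
    """Fraction of planted features whose class has a positive aggregated
    kernel weight (``summary`` is the per-(part, frequency, class) table of
    summed weights from the interpretation stage)."""
    truth = planted_truth(freq_axis_hz, config)
    freq = np.asarray(freq_axis_hz)
    ok = 0
    for part, bins, cls in truth:
        sel = summary[(summary["part"] == part) & (summary["class"] == cls)]
        sel = sel.set_index("feature_index")["summed_weight"]
        nb = len(freq)
        part_offset = PART_NAMES.index(part) * nb
        total = sum(sel.get(part_offset + b, 0.0) for b in bins)
        ok += total > 0
    return ok / len(truth)


def write_cohort_csv(recordings: list[TremorRecording], outdir) -> pd.DataFrame:
    """Write one ``time_s,L,H,U`` CSV per recording plus a manifest CSV."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}_{rec.action}.csv"
        df = pd.DataFrame(
            {
                "time_s": rec.timestamps_s,
                "L": rec.signal[0],
                "H": rec.signal[1],
                "U": rec.signal[2],
            }
        )
        df.to_csv(out / fname, index=False)
        rows.append(
            {"subject_id": rec.subject_id, "class": rec.class_label, "action": rec.action, "file": fname}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_cohort_csv(indir) -> list[TremorRecording]:
    """Read a cohort written by :func:`write_cohort_csv`."""
    from pathlib import Path

    ind = Path(indir)
    manifest = pd.read_csv(ind / "manifest.csv")
    recs = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(ind / row["file"])
        recs.append(
            TremorRecording(
                timestamps_s=df["time_s"].to_numpy(),
                signal=df[["L", "H", "U"]].to_numpy().T,
                class_label=row["class"],
                action=row["action"],
                subject_id=row["subject_id"],
            )
        )
    return recs
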