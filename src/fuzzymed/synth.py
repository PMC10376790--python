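"""Seeded synthetic generators for the four supported data archetypes.

The generators emulate the structure of the study designs the pipeline
targets, so every stage chain can be exercised end to end without access
to protected medical data:

* ``signal`` — two-class single-channel signal records (EEG-like): a
  background class of band-limited 10 Hz oscillation in noise, and a
  seizure-like class of higher-amplitude low-frequency bursts.  Defaults:
  500 records of 23.6 s at 200 Hz, 400/100 class split.
* ``wide`` — a short-and-wide numeric table (more columns than rows, as in
  laboratory blood panels): 78 rows x 186 columns, two classes, a subset of
  informative columns carrying a mean shift.
* ``clinical`` — a mixed numeric/categorical table shaped like an ICU
  cohort: 177 rows, 29 input attributes (binary comorbidity-style flags
  plus log-normal biomarker-style measurements), binary outcome.
* ``expert`` — a tiny pre-fuzzified dataset: 10 samples, three input
  attributes with 2/2/4 terms, a 3-class output, membership degrees drawn
  from a Dirichlet sharpened toward a monotone ground-truth structure
  function, covering 10 of the 16 possible crisp situations.

All generators are fully determined by their seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .fuzzy import FuzzyAttribute, FuzzyDataset
from .preprocess import SignalRecord

__all__ = [
    "SignalSet",
    "SynthConfig",
    "gen_signal_dataset",
    "gen_wide_dataset",
    "gen_clinical_dataset",
    "gen_expert_dataset",
    "expert_structure_function",
    "EXPERT_TERM_COUNTS",
]


@dataclass
class SignalSet:
    records: list[SignalRecord]
    manifest: dict = field(default_factory=dict)


@dataclass
class SynthConfig:
    """Configuration shared by the generators; unused fields are ignored.

    ``effect_size`` scales class separation (amplitude ratio for signals,
    mean shift for tables); 0 gives statistically identical classes.
    """

    archetype: str = "signal"
    seed: int = 0
    n_samples: int = 0  # 0 = archetype default
    class_balance: float = 0.8  # fraction in the majority (negative) class
    effect_size: float = -1.0  # <0 = archetype default
    noise_level: float = -1.0  # <0 = archetype default
    # signal-specific
    duration_s: float = 23.6
    sampling_rate: float = 200.0
    # wide-specific
    n_features: int = 186
    n_informative: int = 20
    # expert-specific
    sharpness: float = 12.0

    def manifest(self, **extra) -> dict:
        d = asdict(self)
        d.update(extra)
        return d


def _resolve(cfg: SynthConfig, attr: str, default: float) -> float:
    v = getattr(cfg, attr)
    return default if v < 0 else v


def gen_signal_dataset(cfg: SynthConfig) -> SignalSet:
    """Two-class labeled signal records.

    Negative class ("background"): 10 Hz sinusoid with random phase, unit
    amplitude, plus Gaussian noise.  Positive class ("seizure"): the same
    background oscillation with an added 3 Hz component amplitude-modulated
    by slow bursts, scaled by the effect size (the burst-to-background
    amplitude ratio).  Effect size 0 makes the classes statistically
    identical.
    """
    n = cfg.n_samples or 500
    effect = _resolve(cfg, "effect_size", 3.0)
    noise = _resolve(cfg, "noise_level", 0.5)
    n_pts = int(round(cfg.duration_s * cfg.sampling_rate))
    if n_pts < 2:
        raise ValueError("duration * sampling_rate must be >= 2 samples")
    n_neg = int(round(cfg.class_balance * n))
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(n_pts) / cfg.sampling_rate
    records = []
    for i in range(n):
        label = "background" if i < n_neg else "seizure"
        phase = rng.uniform(0, 2 * np.pi)
        sig = np.sin(2 * np.pi * 10.0 * t + phase)
        if label == "seizure":
            burst = 0.5 * (1 + np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi)))
            sig = sig + effect * burst * np.sin(2 * np.pi * 3.0 * t + rng.uniform(0, 2 * np.pi))
        sig = sig + rng.normal(0.0, noise, n_pts)
        records.append(
            SignalRecord(samples=sig, sampling_rate=cfg.sampling_rate, label=label, record_id=f"rec{i:04d}")
        )
    manifest = cfg.manifest(
        archetype="signal",
        n_records=n,
        n_negative=n_neg,
        classes=["background", "seizure"],
        model="neg: sin(2*pi*10t+phi)+N(0,noise); pos: effect*burst(0.3Hz)*sin(2*pi*3t+phi)+N(0,noise)",
        synthetic=True,
    )
    return SignalSet(records=records, manifest=manifest)


def gen_wide_dataset(cfg: SynthConfig) -> pd.DataFrame:
    """Short-and-wide two-class numeric table (columns > rows guaranteed).

    Informative columns get class means at -delta/2 and +delta/2 with unit
    noise; the rest are pure standard normal.  The class column is last.
    """
    n = cfg.n_samples or 78
    p = cfg.n_features
    delta = _resolve(cfg, "effect_size", 2.0)
    k_inf = min(cfg.n_informative, p)
    if p <= n:
        raise ValueError("wide archetype requires more feature columns than rows")
    rng = np.random.default_rng(cfg.seed)
    n_ctrl = int(round(cfg.class_balance * n)) if cfg.class_balance != 0.8 else n // 2
    y = np.array(["control"] * n_ctrl + ["tumor"] * (n - n_ctrl))
    x = rng.normal(size=(n, p))
    shift = np.where(y == "tumor", delta / 2.0, -delta / 2.0)
    x[:, :k_inf] += shift[:, None]
    cols = [f"marker_{j + 1:03d}" for j in range(p)]
    df = pd.DataFrame(x, columns=cols)
    df["group"] = y
    return df


def gen_clinical_dataset(cfg: SynthConfig) -> pd.DataFrame:
    """Mixed numeric/categorical clinical-style table with a binary outcome.

    12 binary comorbidity-style flags (class-dependent prevalence) plus 17
    log-normal biomarker-style measurements (class-dependent log-mean
    shift); 29 input attributes total, outcome column ``survival``.
    """
    n = cfg.n_samples or 177
    effect = _resolve(cfg, "effect_size", 1.0)
    rng = np.random.default_rng(cfg.seed)
    n_surv = int(round(cfg.class_balance * n)) if cfg.class_balance != 0.8 else int(round(0.6 * n))
    y = np.array(["survived"] * n_surv + ["died"] * (n - n_surv))
    data: dict[str, np.ndarray] = {}
    base_prev = rng.uniform(0.15, 0.45, size=12)
    for j in range(12):
        p1 = np.clip(base_prev[j] + np.where(y == "died", 0.25 * effect, 0.0), 0.0, 0.95)
        data[f"flag_{j + 1:02d}"] = np.where(rng.random(n) < p1, "yes", "no")
    for j in range(17):
        mu = rng.uniform(0.0, 1.0)
        shift = np.where(y == "died", 0.5 * effect, 0.0)
        data[f"biomarker_{j + 1:02d}"] = np.exp(rng.normal(mu + shift, 0.5, size=n))
    df = pd.DataFrame(data)
    df["survival"] = y
    return df


EXPERT_TERM_COUNTS = (2, 2, 4)

#: The 10 crisp situations the expert dataset covers (of the 16 possible).
EXPERT_SITUATIONS = (
    (0, 0, 0),
    (0, 0, 1),
    (0, 1, 1),
    (1, 0, 2),
    (0, 1, 2),
    (1, 1, 1),
    (1, 0, 3),
    (1, 1, 2),
    (0, 1, 3),
    (1, 1, 3),
)


def expert_structure_function(a1: int, a2: int, a3: int) -> int:
    """Monotone ground-truth outcome for the expert archetype.

    Class 0 (fatal error) whenever the third attribute is at its lowest
    level; class 2 (no complications) when the third attribute is perfect or
    the summed performance levels reach 4; class 1 otherwise.
    Non-decreasing in every argument.
    """
    if a3 == 0:
        return 0
    return 2 if a3 == 3 or a1 + a2 + a3 >= 4 else 1


def gen_expert_dataset(cfg: SynthConfig) -> FuzzyDataset:
    """Pre-fuzzified expert evaluations of 10 of the 16 possible situations.

    Each attribute's membership vector is a Dirichlet draw concentrated on
    the situation's true term with the configured sharpness; in the
    sharpness -> infinity limit the data become exactly crisp and reproduce
    the structure function.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples or len(EXPERT_SITUATIONS)
    situations = list(EXPERT_SITUATIONS)[:n]
    if n > len(EXPERT_SITUATIONS):
        extra = list(itertools.product(range(2), range(2), range(4)))
        situations += extra[: n - len(EXPERT_SITUATIONS)]
    sharp = cfg.sharpness

    def draw(m: int, true_term: int) -> np.ndarray:
        alpha = np.ones(m)
        alpha[true_term] = 1.0 + sharp
        if not np.isfinite(sharp) or sharp > 1e6:
            v = np.zeros(m)
            v[true_term] = 1.0
            return v
        return rng.dirichlet(alpha)

    blocks = [np.zeros((len(situations), m)) for m in EXPERT_TERM_COUNTS] + [
        np.zeros((len(situations), 3))
    ]
    for r, (a1, a2, a3) in enumerate(situations):
        for i, (m, term) in enumerate(zip(EXPERT_TERM_COUNTS, (a1, a2, a3))):
            blocks[i][r] = draw(m, term)
        blocks[3][r] = draw(3, expert_structure_function(a1, a2, a3))
    attributes = [
        FuzzyAttribute("A1", ("error", "ok"), "input"),
        FuzzyAttribute("A2", ("error", "ok"), "input"),
        FuzzyAttribute("A3", ("fatal", "poor", "good", "perfect"), "input"),
        FuzzyAttribute("B", ("B0", "B1", "B2"), "output"),
    ]
    return FuzzyDataset(
        attributes=attributes,
        memberships=blocks,
        provenance=json.dumps(cfg.manifest(archetype="expert", synthetic=True)),
    )
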