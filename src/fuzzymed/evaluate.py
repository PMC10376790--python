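"""Confusion-based classification metrics and the hold-out evaluation protocol.

Metrics follow the standard one-vs-rest definitions:

    Acc  = (TP + TN) / (TP + TN + FP + FN)
    Spec = TN / (TN + FP)
    Sens = TP / (TP + FN)
    Prec = TP / (TP + FP)
    Fsc  = 2 TP / (2 TP + FP + FN)

A zero denominator yields an undefined metric (None), never an exception;
undefined metrics are excluded from macro averages.  Evaluation uses a
seeded 70:30 hold-out split, optionally repeated (random subsampling) with
per-repetition seeds derived deterministically from a master seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fuzzy import FuzzyDataset
from .preprocess import FeatureMatrix

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "evaluate_predictions",
    "macro_report",
    "holdout_split",
    "random_subsampling_eval",
]

METRIC_NAMES = ("accuracy", "specificity", "sensitivity", "precision", "f1")


@dataclass
class ConfusionCounts:
    tp: float = 0.0
    tn: float = 0.0
    fp: float = 0.0
    fn: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    counts: ConfusionCounts
    positive_class: str
    accuracy: float | None = field(init=False)
    specificity: float | None = field(init=False)
    sensitivity: float | None = field(init=False)
    precision: float | None = field(init=False)
    f1: float | None = field(init=False)

    def __post_init__(self) -> None:
        c = self.counts
        if c.total <= 0:
            raise ValueError("all confusion counts are zero")

        def ratio(num: float, den: float) -> float | None:
            return num / den if den > 0 else None

        self.accuracy = ratio(c.tp + c.tn, c.total)
        self.specificity = ratio(c.tn, c.tn + c.fp)
        self.sensitivity = ratio(c.tp, c.tp + c.fn)
        self.precision = ratio(c.tp, c.tp + c.fp)
        self.f1 = ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)

    def as_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "TP": self.counts.tp,
            "TN": self.counts.tn,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
        }


def confusion_counts(
    predicted: Sequence, truth: Sequence, positive_class
) -> ConfusionCounts:
    """One-vs-rest confusion counts against a designated positive class."""
    if len(predicted) != len(truth) or len(predicted) == 0:
        raise ValueError("predicted and truth must be equal-length and non-empty")
    if positive_class not in set(predicted) | set(truth):
        warnings.warn(f"positive class {positive_class!r} absent from predictions and truth")
    c = ConfusionCounts()
    for p, t in zip(predicted, truth):
        if t == positive_class:
            if p == positive_class:
                c.tp += 1
            else:
                c.fn += 1
        else:
            if p == positive_class:
                c.fp += 1
            else:
                c.tn += 1
    return c


def compute_metrics(c: ConfusionCounts, positive_class: str = "positive") -> MetricsReport:
    """The five confusion metrics; zero-denominator cases come back undefined."""
    return MetricsReport(counts=c, positive_class=positive_class)


def evaluate_predictions(predicted: Sequence, truth: Sequence, positive_class) -> MetricsReport:
    return compute_metrics(confusion_counts(predicted, truth, positive_class), str(positive_class))


def macro_report(predicted: Sequence, truth: Sequence, classes: Sequence) -> dict:
    """Per-class one-vs-rest reports plus macro means over defined metrics."""
    per_class = {
        str(c): evaluate_predictions(predicted, truth, c).as_dict() for c in classes
    }
    macro = {}
    for m in METRIC_NAMES:
        vals = [r[m] for r in per_class.values() if r[m] is not None]
        macro[m] = float(np.mean(vals)) if vals else None
    return {"per_class": per_class, "macro": macro}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def holdout_split(
    labels: Sequence,
    train_fraction: float = 0.7,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint train/test index partition (default 70:30).

    Train size is round-half-up(train_fraction * K).  Under stratification
    the per-class train sizes follow largest-remainder rounding so class
    proportions carry over; classes with fewer than 2 samples fall back to
    the unstratified pool with a warning.
    """
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    n_train = min(max(_round_half_up(train_fraction * k), 1), k - 1)

    if not stratified:
        perm = rng.permutation(k)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])

    classes, counts = np.unique(labels, return_counts=True)
    pool_mask = np.zeros(k, dtype=bool)
    strata = []
    for cls, cnt in zip(classes, counts):
        idx = np.where(labels == cls)[0]
        if cnt < 2:
            warnings.warn(f"class {cls!r} has < 2 samples; not stratified")
            pool_mask[idx] = True
        else:
            strata.append(idx)
    pool = np.where(pool_mask)[0]
    n_strat_train = n_train
    # Largest-remainder apportionment of the train budget across strata+pool.
    groups = strata + ([pool] if pool.size else [])
    quotas = [train_fraction * g.size for g in groups]
    floors = [int(math.floor(q)) for q in quotas]
    short = n_strat_train - sum(floors)
    order = np.argsort([f - q for f, q in zip(floors, quotas)])  # largest remainder first
    takes = list(floors)
    for pos in order:
        if short <= 0:
            break
        if takes[pos] < groups[pos].size:
            takes[pos] += 1
            short -= 1
    # If rounding overshot (short < 0), trim from smallest remainders.
    for pos in order[::-1]:
        if short >= 0:
            break
        if takes[pos] > 0:
            takes[pos] -= 1
            short += 1
    train_idx: list[int] = []
    test_idx: list[int] = []
    for g, take in zip(groups, takes):
        perm = rng.permutation(g)
        train_idx.extend(perm[:take])
        test_idx.extend(perm[take:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


def split_dataset(ds: FuzzyDataset | FeatureMatrix, train_idx: np.ndarray, test_idx: np.ndarray):
    """Materialize a train/test pair from index arrays."""
    if isinstance(ds, FuzzyDataset):
        return ds.subset(train_idx), ds.subset(test_idx)
    return (
        FeatureMatrix(
            values=ds.values[train_idx],
            feature_names=list(ds.feature_names),
            labels=[ds.labels[i] for i in train_idx],
        ),
        FeatureMatrix(
            values=ds.values[test_idx],
            feature_names=list(ds.feature_names),
            labels=[ds.labels[i] for i in test_idx],
        ),
    )


def random_subsampling_eval(
    ds: FuzzyDataset,
    fit_predict: Callable[[FuzzyDataset, FuzzyDataset], list],
    positive_class,
    reps: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> dict:
    """Repeated seeded hold-out evaluation (random subsampling).

    ``fit_predict(train, test)`` must return predicted class labels for the
    test rows.  Per-repetition seeds are drawn deterministically from the
    master seed.  Returns per-rep reports plus mean/sd summaries over the
    defined metrics.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    out_attr = ds.output_attribute
    labels = np.asarray(
        [out_attr.term_labels[j] for j in np.argmax(ds.memberships[ds.output_index], axis=1)]
    )
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=reps)
    reports = []
    for r in range(reps):
        tr, te = holdout_split(labels, train_fraction, stratified=stratified, seed=int(rep_seeds[r]))
        train, test = ds.subset(tr), ds.subset(te)
        try:
            predicted = fit_predict(train, test)
        except Exception as exc:  # attach the repetition index for diagnosis
            raise RuntimeError(f"classifier failed on repetition {r}") from exc
        reports.append(evaluate_predictions(predicted, list(labels[te]), positive_class))
    summary = {}
    for m in METRIC_NAMES:
        vals = [getattr(rep, m) for rep in reports if getattr(rep, m) is not None]
        summary[m] = {
            "mean": float(np.mean(vals)) if vals else None,
            "sd": float(np.std(vals, ddof=0)) if vals else None,
        }
    return {"reports": reports, "summary": summary}
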