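"""Fuzzification of crisp columns via per-attribute 1-D fuzzy C-means.

Each numeric column becomes a fuzzy attribute whose linguistic terms are the
ascending-ordered FCM cluster centers; the FCM soft-membership formula then
serves as the term membership function (degrees always sum to 1, and a value
sitting exactly on a center belongs fully to that term).  Categorical columns
and the class column become degenerate crisp attributes (one term per
category, one-hot degrees).  Already-fuzzy "expert" column blocks are
validated and passed through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fuzzy import FuzzyAttribute, FuzzyDataset, validate_membership

__all__ = [
    "FCMAttribute",
    "FCMModel",
    "fcm_fit",
    "fcm_membership",
    "fuzzify_dataset",
    "term_labels_for",
]

#: Distances below this are an exact center hit (crisp membership).
_CENTER_EPS = 1e-12


def term_labels_for(m: int) -> list[str]:
    """Autogenerated ascending linguistic labels: low .. high."""
    if m == 2:
        return ["low", "high"]
    if m == 3:
        return ["low", "medium", "high"]
    return ["low"] + [f"mid{i}" for i in range(1, m - 1)] + ["high"]


@dataclass
class FCMAttribute:
    """Fitted 1-D FCM fuzzifier for one numeric column."""

    column: str
    centers: np.ndarray  # strictly increasing, length m >= 2
    q: float = 2.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).ravel()
        if self.centers.size < 2:
            raise ValueError("need >= 2 cluster centers")
        if not (np.diff(self.centers) > 0).all():
            raise ValueError("centers must be strictly increasing")
        if self.q <= 1:
            raise ValueError("fuzzifier exponent q must exceed 1")


@dataclass
class FCMModel:
    """Per-column FCM fuzzifiers, keyed by source column name."""

    attributes: dict[str, FCMAttribute] = field(default_factory=dict)


def _fcm_memberships(x: np.ndarray, centers: np.ndarray, q: float) -> np.ndarray:
    """Standard FCM membership matrix for points ``x`` given fixed centers.

    mu_j(x) = 1 / sum_l (d_j/d_l)^(2/(q-1)); exact center hits are crisp.
    """
    d = np.abs(x[:, None] - centers[None, :])
    u = np.zeros((x.size, centers.size))
    hit = d < _CENTER_EPS
    on_center = hit.any(axis=1)
    if on_center.any():
        rows = np.where(on_center)[0]
        u[rows, np.argmax(hit[rows], axis=1)] = 1.0
    free = ~on_center
    if free.any():
        p = 2.0 / (q - 1.0)
        inv = d[free] ** (-p)
        u[free] = inv / inv.sum(axis=1, keepdims=True)
    return u


def fcm_fit(
    values,
    m_terms: int,
    q: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    n_restarts: int = 0,
    column: str = "x",
) -> FCMAttribute:
    """Fit 1-D fuzzy C-means by alternating optimization.

    Initialized at the ``m_terms`` equally spaced quantiles of the data
    (deterministic); optional seeded random restarts keep the solution with
    the lowest FCM objective.  Iterates until the largest center shift drops
    below ``tol`` or ``max_iter`` is reached.  Centers are returned in
    ascending order, which fixes the term semantics (low .. high).
    """
    x = np.asarray(values, dtype=float).ravel()
    if m_terms < 2:
        raise ValueError("m_terms must be >= 2")
    if q <= 1:
        raise ValueError("q must exceed 1")
    uniq = np.unique(x)
    if uniq.size == 1:
        raise ValueError(
            f"column {column!r} is constant; encode it as categorical instead of fuzzifying"
        )
    if uniq.size < m_terms:
        raise ValueError(
            f"column {column!r}: {uniq.size} distinct values < {m_terms} requested terms"
        )

    def run(centers0: np.ndarray) -> tuple[np.ndarray, float]:
        centers = centers0.astype(float).copy()
        for _ in range(max_iter):
            u = _fcm_memberships(x, centers, q)
            uq = u**q
            denom = uq.sum(axis=0)
            # A cluster starved of mass is re-seeded at the farthest point.
            starved = denom < _CENTER_EPS
            if starved.any():
                d = np.abs(x[:, None] - centers[None, :]).min(axis=1)
                centers[starved] = x[np.argmax(d)]
                continue
            new = (uq * x[:, None]).sum(axis=0) / denom
            shift = np.max(np.abs(new - centers))
            centers = new
            if shift < tol:
                break
        u = _fcm_memberships(x, centers, q)
        obj = float((u**q * (x[:, None] - centers[None, :]) ** 2).sum())
        return centers, obj

    quantiles = np.quantile(x, np.linspace(0, 1, 2 * m_terms + 1)[1::2])
    starts = [np.asarray(quantiles, float)]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        starts.append(rng.choice(uniq, size=m_terms, replace=False))
    best = min((run(c0) for c0 in starts), key=lambda t: t[1])
    centers = np.sort(best[0])
    if not (np.diff(centers) > _CENTER_EPS).all():
        # Collapsed centers: fall back to hard quantile centers.
        centers = np.asarray(quantiles, float)
    return FCMAttribute(column=column, centers=centers, q=q)


def fcm_membership(x: float, model: FCMModel | FCMAttribute, attr: str | None = None) -> np.ndarray:
    """Membership vector of a scalar under a fitted FCM attribute.

    Degrees sum to 1; a value equal to a center belongs fully to that term.
    Extrapolation beyond the data range is allowed.
    """
    fa = model if isinstance(model, FCMAttribute) else model.attributes[attr]
    return _fcm_memberships(np.asarray([x], float), fa.centers, fa.q)[0]


def _one_hot(series: pd.Series, categories: list) -> np.ndarray:
    k = len(series)
    u = np.zeros((k, len(categories)))
    index = {c: i for i, c in enumerate(categories)}
    for r, v in enumerate(series):
        if pd.isna(v):
            u[r, :] = 1.0 / len(categories)
            warnings.warn(f"missing categorical value at row {r}; using uniform membership")
        elif v in index:
            u[r, index[v]] = 1.0
        else:
            u[r, :] = 1.0 / len(categories)
            warnings.warn(f"unseen category {v!r} at row {r}; using uniform membership")
    return u


def fuzzify_dataset(
    tbl: pd.DataFrame,
    term_counts: dict[str, int],
    class_column: str,
    *,
    categorical_columns: list[str] | None = None,
    q: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    provenance: str = "",
) -> tuple[FCMModel, FuzzyDataset]:
    """Convert a crisp table into a FuzzyDataset.

    Numeric columns listed in ``term_counts`` are fuzzified by FCM;
    categorical columns and the class column become crisp one-hot attributes.
    Missing numeric values get uniform memberships (maximal ignorance).
    """
    if class_column not in tbl.columns:
        raise ValueError(f"class column {class_column!r} not in table")
    categorical_columns = list(categorical_columns or [])
    numeric_cols = [c for c in tbl.columns if c != class_column and c not in categorical_columns]
    missing_spec = [c for c in numeric_cols if c not in term_counts]
    if missing_spec:
        raise ValueError(f"term_counts missing for numeric columns: {missing_spec}")

    model = FCMModel()
    attributes: list[FuzzyAttribute] = []
    blocks: list[np.ndarray] = []

    for col in numeric_cols:
        x = pd.to_numeric(tbl[col], errors="raise")
        valid = x.dropna().to_numpy(float)
        fa = fcm_fit(
            valid, term_counts[col], q=q, tol=tol, max_iter=max_iter, seed=seed, column=col
        )
        model.attributes[col] = fa
        m = fa.centers.size
        u = np.empty((len(tbl), m))
        isna = x.isna().to_numpy()
        if isna.any():
            warnings.warn(f"column {col!r}: {int(isna.sum())} missing values get uniform membership")
            u[isna] = 1.0 / m
        if (~isna).any():
            u[~isna] = _fcm_memberships(x.to_numpy(float)[~isna], fa.centers, fa.q)
        attributes.append(FuzzyAttribute(name=col, term_labels=tuple(term_labels_for(m)), role="input"))
        blocks.append(u)

    for col in categorical_columns:
        cats = sorted(tbl[col].dropna().unique(), key=str)
        if len(cats) < 2:
            cats = list(cats) + ["__other__"] * (2 - len(cats))
        attributes.append(
            FuzzyAttribute(name=col, term_labels=tuple(str(c) for c in cats), role="input")
        )
        blocks.append(_one_hot(tbl[col], cats))

    classes = sorted(tbl[class_column].dropna().unique(), key=str)
    if len(classes) < 2:
        raise ValueError("class column must have >= 2 classes")
    attributes.append(
        FuzzyAttribute(name=class_column, term_labels=tuple(str(c) for c in classes), role="output")
    )
    blocks.append(_one_hot(tbl[class_column], classes))

    ds = FuzzyDataset(attributes=attributes, memberships=blocks, provenance=provenance)
    return model, ds


def validate_expert_dataset(ds: FuzzyDataset) -> FuzzyDataset:
    """Pass-through validation for pre-fuzzified expert data.

    Requires all degrees already in [0, 1]; raises otherwise.
    """
    for attr, block in zip(ds.attributes, ds.memberships):
        validate_membership(block.ravel(), name=attr.name)
    return ds
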