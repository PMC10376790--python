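"""Fuzzy decision-tree induction and inference, plus a fuzzy naive Bayes baseline.

The tree is grown recursively.  Every sample carries a branch mass (product
of the membership degrees of the branches taken so far); at each node the
unused input attribute with the highest fuzzy mutual information against the
class — computed on the node's mass-weighted frequency table — is chosen as
the split.  Two pruning parameters control the size: ``alpha`` (a node whose
mass fraction of the training total does not exceed alpha becomes a leaf)
and ``beta`` (a node whose dominant-class confidence reaches beta becomes a
leaf).  Lowering alpha or raising beta therefore enlarges the tree.

Inference aggregates all root-to-leaf paths: each path contributes its leaf
confidence weighted by the product of branch memberships along the path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fuzzy import (
    FuzzyAttribute,
    FuzzyDataset,
    fuzzy_frequency_table,
    fuzzy_mutual_information,
)

__all__ = [
    "FDTNode",
    "FDTModel",
    "FNBModel",
    "induct_fdt",
    "fdt_classify",
    "fdt_predict_class",
    "fdt_decision_table",
    "fdt_rules",
    "fdt_to_dot",
    "fnb_fit",
    "fnb_classify",
    "fnb_predict_class",
]


@dataclass
class FDTNode:
    """Internal node (attribute test, one child per term) or leaf (class confidences)."""

    attribute_index: Optional[int] = None
    children: list["FDTNode"] = field(default_factory=list)
    confidence: Optional[np.ndarray] = None  # set on leaves, sums to 1
    mass: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.attribute_index is None

    def count_nodes(self) -> int:
        return 1 + sum(c.count_nodes() for c in self.children)

    def depth(self) -> int:
        return 0 if self.is_leaf else 1 + max(c.depth() for c in self.children)


@dataclass
class FDTModel:
    root: FDTNode
    alpha: float
    beta: float
    attributes: list[FuzzyAttribute]
    output_index: int
    tnorm: str = "product"
    induction_log: list[dict] = field(default_factory=list)

    @property
    def input_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.attributes) if a.role == "input"]

    @property
    def classes(self) -> tuple[str, ...]:
        return self.attributes[self.output_index].term_labels

    def count_nodes(self) -> int:
        return self.root.count_nodes()


def induct_fdt(
    ds: FuzzyDataset,
    alpha: float = 0.01,
    beta: float = 0.95,
    *,
    tnorm: str = "product",
) -> FDTModel:
    """Grow a fuzzy decision tree on a FuzzyDataset.

    Stops expanding a node (making it a leaf) when any of: the dominant-class
    confidence reaches ``beta``; the node's mass fraction does not exceed
    ``alpha`` (for alpha > 0); or no unused input attribute remains.  A
    zero-mass node becomes a leaf inheriting its parent's confidence.  Ties
    in the split score go to the lowest attribute index.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    y = ds.memberships[ds.output_index]
    total_mass = float(y.sum())
    if total_mass <= 0:
        raise ValueError("dataset carries no class mass")
    log: list[dict] = []

    def grow(weights: np.ndarray, unused: list[int], parent_conf: np.ndarray, depth: int) -> FDTNode:
        class_mass = weights @ y
        mass = float(class_mass.sum())
        if mass <= 1e-15:
            return FDTNode(confidence=parent_conf.copy(), mass=0.0)
        conf = class_mass / mass
        dominant = float(conf.max())
        frac = mass / total_mass
        if dominant >= beta or (alpha > 0 and frac <= alpha) or not unused:
            return FDTNode(confidence=conf, mass=mass)
        scores = []
        for i in unused:
            ft = fuzzy_frequency_table(ds, i, tnorm=tnorm, sample_weights=weights)
            scores.append(fuzzy_mutual_information(ft) if ft.total > 0 else 0.0)
        # lowest attribute index wins ties (within rounding) in the split score
        top = max(scores)
        best_pos = next(p for p, s in enumerate(scores) if s >= top - 1e-12)
        best_attr = unused[best_pos]
        log.append(
            {"depth": depth, "attribute": ds.attributes[best_attr].name, "score": scores[best_pos]}
        )
        remaining = [i for i in unused if i != best_attr]
        a = ds.memberships[best_attr]
        children = [
            grow(weights * a[:, j], remaining, conf, depth + 1) for j in range(a.shape[1])
        ]
        return FDTNode(attribute_index=best_attr, children=children, mass=mass)

    root = grow(np.ones(ds.n_samples), ds.input_indices, np.full(y.shape[1], 1.0 / y.shape[1]), 0)
    return FDTModel(
        root=root,
        alpha=alpha,
        beta=beta,
        attributes=list(ds.attributes),
        output_index=ds.output_index,
        tnorm=tnorm,
        induction_log=log,
    )


def _check_instance(model: FDTModel | "FNBModel", instance: Sequence[np.ndarray]) -> list[np.ndarray]:
    inputs = [i for i, a in enumerate(model.attributes) if a.role == "input"]
    if len(instance) != len(inputs):
        raise ValueError(f"instance has {len(instance)} attribute values, expected {len(inputs)}")
    vecs = []
    for pos, i in enumerate(inputs):
        v = np.asarray(instance[pos], dtype=float).ravel()
        m = model.attributes[i].n_terms
        if v.size != m:
            raise ValueError(
                f"attribute {model.attributes[i].name!r}: membership vector of length "
                f"{v.size}, expected {m}"
            )
        vecs.append(v)
    return vecs


def fdt_classify(model: FDTModel, instance: Sequence[np.ndarray]) -> np.ndarray:
    """Class-confidence vector for one instance (sums to 1).

    Confidence = sum over root-to-leaf paths of (product of branch
    memberships along the path) x leaf confidence, renormalized.
    """
    vecs = _check_instance(model, instance)
    inputs = [i for i, a in enumerate(model.attributes) if a.role == "input"]
    by_attr = dict(zip(inputs, vecs))
    n_classes = model.attributes[model.output_index].n_terms
    out = np.zeros(n_classes)

    def walk(node: FDTNode, weight: float) -> None:
        if weight <= 0.0:
            return
        if node.is_leaf:
            out[:] += weight * node.confidence
            return
        mu = by_attr[node.attribute_index]
        for j, child in enumerate(node.children):
            walk(child, weight * mu[j])

    walk(model.root, 1.0)
    total = out.sum()
    if total <= 0:
        return np.full(n_classes, 1.0 / n_classes)
    return out / total


def fdt_predict_class(model: FDTModel, instance: Sequence[np.ndarray]) -> str:
    """Crisp decision: argmax confidence, lowest class index on ties."""
    conf = fdt_classify(model, instance)
    return model.classes[int(np.argmax(conf))]


def fdt_decision_table(model: FDTModel) -> pd.DataFrame:
    """Exhaustive decision table: one row per crisp combination of input terms.

    Row count is the product of the input attributes' term counts; each row
    records the crisp prediction and the full confidence vector.
    """
    inputs = [i for i, a in enumerate(model.attributes) if a.role == "input"]
    term_ranges = [range(model.attributes[i].n_terms) for i in inputs]
    rows = []
    for combo in itertools.product(*term_ranges):
        instance = []
        for pos, i in enumerate(inputs):
            v = np.zeros(model.attributes[i].n_terms)
            v[combo[pos]] = 1.0
            instance.append(v)
        conf = fdt_classify(model, instance)
        row = {
            model.attributes[i].name: model.attributes[i].term_labels[combo[pos]]
            for pos, i in enumerate(inputs)
        }
        row["prediction"] = model.classes[int(np.argmax(conf))]
        for k, cls in enumerate(model.classes):
            row[f"confidence:{cls}"] = conf[k]
        rows.append(row)
    return pd.DataFrame(rows)


def fdt_rules(model: FDTModel) -> list[str]:
    """Human-readable rules, one per leaf: IF ... AND ... THEN class [conf]."""
    rules: list[str] = []

    def walk(node: FDTNode, conds: list[str]) -> None:
        if node.is_leaf:
            k = int(np.argmax(node.confidence))
            cond = " AND ".join(conds) if conds else "TRUE"
            rules.append(
                f"IF {cond} THEN class {model.classes[k]} [{node.confidence[k]:.2f}]"
            )
            return
        attr = model.attributes[node.attribute_index]
        for j, child in enumerate(node.children):
            walk(child, conds + [f"{attr.name} is {attr.term_labels[j]}"])

    walk(model.root, [])
    return rules


def fdt_to_dot(model: FDTModel) -> str:
    """Graphviz DOT rendering of the tree."""
    lines = ["digraph FDT {", "  node [shape=box];"]
    counter = itertools.count()

    def walk(node: FDTNode) -> int:
        nid = next(counter)
        if node.is_leaf:
            k = int(np.argmax(node.confidence))
            lines.append(
                f'  n{nid} [label="{model.classes[k]}\\n{node.confidence[k]:.2f}", style=filled];'
            )
        else:
            attr = model.attributes[node.attribute_index]
            lines.append(f'  n{nid} [label="{attr.name}?"];')
            for j, child in enumerate(node.children):
                cid = walk(child)
                lines.append(f'  n{nid} -> n{cid} [label="{attr.term_labels[j]}"];')
        return nid

    walk(model.root)
    lines.append("}")
    return "\n".join(lines)


@dataclass
class FNBModel:
    """Fuzzy naive Bayes: membership-mass priors and per-term class conditionals."""

    attributes: list[FuzzyAttribute]
    output_index: int
    priors: np.ndarray  # n_classes, sums to 1
    conditionals: dict[int, np.ndarray]  # attr index -> m_i x n_classes, columns sum to 1
    smoothing: float = 1.0

    @property
    def classes(self) -> tuple[str, ...]:
        return self.attributes[self.output_index].term_labels


def fnb_fit(ds: FuzzyDataset, smoothing: float = 1.0) -> FNBModel:
    """Estimate priors and conditionals from membership masses.

    Prior(k) is the class-k membership mass over the total; the conditional
    for (attribute i, term j, class k) is the joint mass with Laplace-style
    smoothing, normalized per class over terms.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    y = ds.memberships[ds.output_index]
    if ds.n_samples == 0 or y.sum() <= 0:
        raise ValueError("empty dataset")
    class_mass = y.sum(axis=0)
    priors = class_mass / class_mass.sum()
    conditionals: dict[int, np.ndarray] = {}
    for i in ds.input_indices:
        joint = ds.memberships[i].T @ y + smoothing  # m_i x n_classes
        col = joint.sum(axis=0)
        col[col == 0] = 1.0
        conditionals[i] = joint / col
    return FNBModel(
        attributes=list(ds.attributes),
        output_index=ds.output_index,
        priors=priors,
        conditionals=conditionals,
        smoothing=smoothing,
    )


def fnb_classify(model: FNBModel, instance: Sequence[np.ndarray]) -> np.ndarray:
    """Posterior class memberships: prior(k) x prod_i sum_j mu_ij cond(i,j,k)."""
    vecs = _check_instance(model, instance)
    inputs = [i for i, a in enumerate(model.attributes) if a.role == "input"]
    post = model.priors.astype(float).copy()
    for pos, i in enumerate(inputs):
        post *= vecs[pos] @ model.conditionals[i]
    total = post.sum()
    if total <= 0:
        return np.full(post.size, 1.0 / post.size)
    return post / total


def fnb_predict_class(model: FNBModel, instance: Sequence[np.ndarray]) -> str:
    conf = fnb_classify(model, instance)
    return model.classes[int(np.argmax(conf))]
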