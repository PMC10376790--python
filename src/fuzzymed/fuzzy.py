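"""Fuzzy-set primitives and information estimates for fuzzy decision-tree induction.

A fuzzy attribute :math:`A_i` takes values over :math:`m_i \\ge 2` linguistic
terms; a sample's value for the attribute is a membership vector, one degree
in [0, 1] per term.  The information score used to select split attributes is
fuzzy Shannon mutual information computed over t-norm joint membership
masses: it quantifies, in bits, the degree of influence of an input attribute
on the class attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "FuzzyAttribute",
    "FuzzyDataset",
    "FrequencyTable",
    "cardinality",
    "fuzzy_frequency_table",
    "fuzzy_mutual_information",
    "entropy",
    "validate_membership",
    "TNORMS",
]

#: Mass threshold below which joint masses are treated as exactly zero
#: (avoids log underflow; 0*log 0 := 0 convention).
EPS_MASS = 1e-12

TNORMS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "product": np.multiply,
    "min": np.minimum,
}


def validate_membership(degrees: Sequence[float] | np.ndarray, *, name: str = "membership") -> np.ndarray:
    """Validate a degree sequence and return it as a float array.

    Raises ``ValueError`` naming the first offending index if any degree
    falls outside [0, 1].
    """
    arr = np.asarray(degrees, dtype=float)
    bad = np.where((arr < 0.0) | (arr > 1.0) | ~np.isfinite(arr))[0]
    if bad.size:
        raise ValueError(
            f"{name}: degree at index {bad[0]} is {arr[bad[0]]!r}, outside [0, 1]"
        )
    return arr


def cardinality(degrees: Sequence[float] | np.ndarray) -> float:
    """Cardinality M(A) of a fuzzy set: the sum of its membership degrees.

    For a crisp set this reduces to the element count; it is additive over
    concatenation of degree sequences.
    """
    arr = validate_membership(degrees, name="cardinality")
    return float(arr.sum())


@dataclass(frozen=True)
class FuzzyAttribute:
    """A linguistic attribute with ``m_i >= 2`` named terms."""

    name: str
    term_labels: tuple[str, ...]
    role: Literal["input", "output"] = "input"

    def __post_init__(self) -> None:
        if len(self.term_labels) < 2:
            raise ValueError(f"attribute {self.name!r}: needs >= 2 terms, got {len(self.term_labels)}")
        if len(set(self.term_labels)) != len(self.term_labels):
            raise ValueError(f"attribute {self.name!r}: duplicate term labels")
        object.__setattr__(self, "term_labels", tuple(self.term_labels))

    @property
    def n_terms(self) -> int:
        return len(self.term_labels)


@dataclass
class FuzzyDataset:
    """K samples of fuzzy attribute values.

    ``memberships[i]`` is the K x m_i degree matrix for ``attributes[i]``.
    Exactly one attribute has role ``"output"`` (the class attribute).
    """

    attributes: list[FuzzyAttribute]
    memberships: list[np.ndarray]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.attributes) != len(self.memberships):
            raise ValueError("attributes and membership blocks misaligned")
        out = [a for a in self.attributes if a.role == "output"]
        if len(out) != 1:
            raise ValueError(f"expected exactly one output attribute, found {len(out)}")
        k = None
        for attr, block in zip(self.attributes, self.memberships):
            m = validate_membership(np.asarray(block, float).ravel(), name=attr.name).reshape(np.shape(block))
            if m.ndim != 2 or m.shape[1] != attr.n_terms:
                raise ValueError(
                    f"attribute {attr.name!r}: block shape {m.shape} does not match {attr.n_terms} terms"
                )
            if k is None:
                k = m.shape[0]
            elif m.shape[0] != k:
                raise ValueError("membership blocks disagree on sample count")
        if k is None or k < 1:
            raise ValueError("dataset needs at least one sample")
        self.memberships = [np.asarray(b, float) for b in self.memberships]

    @property
    def n_samples(self) -> int:
        return self.memberships[0].shape[0]

    @property
    def output_index(self) -> int:
        return next(i for i, a in enumerate(self.attributes) if a.role == "output")

    @property
    def input_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.attributes) if a.role == "input"]

    @property
    def output_attribute(self) -> FuzzyAttribute:
        return self.attributes[self.output_index]

    def subset(self, rows: np.ndarray) -> "FuzzyDataset":
        """Row-subset view (copies), preserving attribute metadata."""
        return FuzzyDataset(
            attributes=list(self.attributes),
            memberships=[m[rows] for m in self.memberships],
            provenance=self.provenance,
        )


@dataclass
class FrequencyTable:
    """Joint membership-mass table for one input attribute vs. the class.

    ``cells[j, k]`` holds the t-norm mass accumulated over samples for
    (input term j, class k).
    """

    cells: np.ndarray
    row_marginals: np.ndarray = field(init=False)
    col_marginals: np.ndarray = field(init=False)
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.ndim != 2:
            raise ValueError("frequency table must be 2-D")
        if (self.cells < -EPS_MASS).any():
            raise ValueError("negative mass in frequency table")
        self.cells = np.clip(self.cells, 0.0, None)
        self.row_marginals = self.cells.sum(axis=1)
        self.col_marginals = self.cells.sum(axis=0)
        self.total = float(self.cells.sum())


def fuzzy_frequency_table(
    ds: FuzzyDataset,
    input_index: int,
    *,
    tnorm: str = "product",
    sample_weights: np.ndarray | None = None,
) -> FrequencyTable:
    """Joint (input term x class) membership mass table.

    cell(j, k) = sum over samples of T(mu_{A_i,j}, mu_{B,k}), optionally
    weighted per sample (used during tree induction where the weight is the
    accumulated branch mass of the node).
    """
    if ds.attributes[input_index].role != "input":
        raise ValueError(f"attribute index {input_index} is not an input attribute")
    if ds.n_samples == 0:
        raise ValueError("empty dataset")
    t = TNORMS[tnorm]
    a = ds.memberships[input_index]  # K x m_i
    b = ds.memberships[ds.output_index]  # K x m_B
    # T applied pairwise over the (term, class) grid for each sample.
    joint = t(a[:, :, None], b[:, None, :])  # K x m_i x m_B
    if sample_weights is not None:
        joint = joint * np.asarray(sample_weights, float)[:, None, None]
    return FrequencyTable(cells=joint.sum(axis=0))


def entropy(masses: np.ndarray) -> float:
    """Shannon entropy (bits) of a nonnegative mass vector, normalized internally."""
    m = np.asarray(masses, dtype=float)
    total = m.sum()
    if total <= EPS_MASS:
        raise ValueError("zero total mass")
    p = m / total
    p = p[p > EPS_MASS]
    return float(-(p * np.log2(p)).sum())


def fuzzy_mutual_information(ft: FrequencyTable) -> float:
    """Mutual information I(A_i; B) in bits over the normalized mass table.

    The score of an input attribute's influence on the class: 0 under
    independence, H(B) when the attribute determines the class.  Clipped at
    zero against -1e-12-scale rounding.
    """
    if ft.total <= EPS_MASS:
        raise ValueError("zero total mass in frequency table")
    p = ft.cells / ft.total
    pr = ft.row_marginals / ft.total
    pc = ft.col_marginals / ft.total
    mi = 0.0
    for j in range(p.shape[0]):
        for k in range(p.shape[1]):
            pjk = p[j, k]
            if pjk > EPS_MASS:
                mi += pjk * np.log2(pjk / (pr[j] * pc[k]))
    return max(float(mi), 0.0)
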