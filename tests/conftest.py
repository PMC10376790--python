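import numpy as np
import pytest

from fuzzymed.fuzzy import FuzzyAttribute, FuzzyDataset


@pytest.fixture
def toy_fuzzy_dataset() -> FuzzyDataset:
    """4 samples, two 2-term inputs, binary output, mildly fuzzy degrees."""
    rng = np.random.default_rng(42)
    a = rng.dirichlet((2, 2), size=4)
    b = rng.dirichlet((3, 1), size=4)
    y = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    return FuzzyDataset(
        attributes=[
            FuzzyAttribute("A1", ("low", "high"), "input"),
            FuzzyAttribute("A2", ("low", "high"), "input"),
            FuzzyAttribute("B", ("neg", "pos"), "output"),
        ],
        memberships=[a, b, y],
    )


def crisp_boolean_dataset(func_table):
    """FuzzyDataset for one Boolean function of two binary attributes.

    ``func_table`` maps (a1, a2) in {0,1}^2 to a class in {0,1}; the dataset
    holds the four crisp rows of the truth table.
    """
    rows = sorted(func_table)
    a1 = np.zeros((4, 2))
    a2 = np.zeros((4, 2))
    y = np.zeros((4, 2))
    for r, (v1, v2) in enumerate(rows):
        a1[r, v1] = 1.0
        a2[r, v2] = 1.0
        y[r, func_table[(v1, v2)]] = 1.0
    return FuzzyDataset(
        attributes=[
            FuzzyAttribute("A1", ("f", "t"), "input"),
            FuzzyAttribute("A2", ("f", "t"), "input"),
            FuzzyAttribute("B", ("c0", "c1"), "output"),
        ],
        memberships=[a1, a2, y],
    )
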