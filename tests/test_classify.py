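"""Fuzzy decision-tree induction/inference and fuzzy naive Bayes."""

import itertools

import numpy as np
import pytest

from conftest import crisp_boolean_dataset
from fuzzymed.classify import (
    fdt_classify,
    fdt_decision_table,
    fdt_predict_class,
    fdt_rules,
    fdt_to_dot,
    fnb_classify,
    fnb_fit,
    fnb_predict_class,
    induct_fdt,
)
from fuzzymed.fuzzy import FuzzyAttribute, FuzzyDataset
from fuzzymed.synth import SynthConfig, gen_expert_dataset


# ---------------------------------------------------------------------------
# Brute-force crisp ID3 oracle (independent of the implementation under test)


def _entropy(counts):
    p = np.asarray(counts, float)
    p = p[p > 0] / p.sum()
    return float(-(p * np.log2(p)).sum())


def id3_oracle(rows, unused, parent_majority=0):
    """rows: list of ((a1, a2), cls).  Returns nested dict tree."""
    if not rows:
        return {"leaf": parent_majority}
    counts = [0, 0]
    for _, c in rows:
        counts[c] += 1
    majority = int(np.argmax(counts))  # lowest index on ties
    if counts[0] == 0 or counts[1] == 0 or not unused:
        return {"leaf": majority}
    gains = []
    for a in unused:
        h = _entropy(counts)
        for v in (0, 1):
            sub = [c for (vals, c) in rows if vals[a] == v]
            if sub:
                subcounts = [sub.count(0), sub.count(1)]
                h -= len(sub) / len(rows) * _entropy(subcounts)
        gains.append(h)
    best = unused[int(np.argmax(gains))]
    rest = [a for a in unused if a != best]
    return {
        "split": best,
        "children": [
            id3_oracle([(vals, c) for (vals, c) in rows if vals[best] == v], rest, majority)
            for v in (0, 1)
        ],
    }


def _same_structure(node, oracle):
    if "leaf" in oracle:
        assert node.is_leaf
        assert int(np.argmax(node.confidence)) == oracle["leaf"]
        return
    assert not node.is_leaf
    assert node.attribute_index == oracle["split"]
    for child, ochild in zip(node.children, oracle["children"]):
        _same_structure(child, ochild)


ALL_BOOLEAN_FUNCTIONS = [
    {pt: (bits >> i) & 1 for i, pt in enumerate(itertools.product((0, 1), repeat=2))}
    for bits in range(16)
]


class TestCrispReduction:
    @pytest.mark.parametrize("func", ALL_BOOLEAN_FUNCTIONS, ids=lambda f: "".join(map(str, f.values())))
    def test_matches_information_gain_oracle(self, func):
        """On crisp truth tables FDT induction equals classical ID3."""
        ds = crisp_boolean_dataset(func)
        model = induct_fdt(ds, alpha=0.0, beta=1.0)
        rows = [((v1, v2), func[(v1, v2)]) for v1, v2 in sorted(func)]
        oracle = id3_oracle(rows, [0, 1])
        _same_structure(model.root, oracle)
        # training accuracy 1.0 on consistent crisp data
        for (v1, v2), cls in rows:
            inst = [np.eye(2)[v1], np.eye(2)[v2]]
            assert fdt_predict_class(model, inst) == ("c0", "c1")[cls]

    def test_and_function_depth_two(self):
        func = {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 1}
        model = induct_fdt(crisp_boolean_dataset(func), alpha=0.01, beta=0.99)
        assert model.root.depth() == 2


class TestInduction:
    def test_single_class_single_leaf(self):
        ds = FuzzyDataset(
            attributes=[
                FuzzyAttribute("A", ("l", "h"), "input"),
                FuzzyAttribute("B", ("x", "y"), "output"),
            ],
            memberships=[np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([[1.0, 0.0], [1.0, 0.0]])],
        )
        model = induct_fdt(ds, alpha=0.0, beta=0.9)
        assert model.root.is_leaf
        np.testing.assert_allclose(model.root.confidence, [1.0, 0.0])

    def test_alpha_one_gives_root_leaf(self, toy_fuzzy_dataset):
        model = induct_fdt(toy_fuzzy_dataset, alpha=1.0, beta=1.0)
        assert model.count_nodes() == 1

    def test_single_sample_is_single_leaf(self):
        ds = FuzzyDataset(
            attributes=[
                FuzzyAttribute("A", ("l", "h"), "input"),
                FuzzyAttribute("B", ("x", "y"), "output"),
            ],
            memberships=[np.array([[0.7, 0.3]]), np.array([[0.0, 1.0]])],
        )
        model = induct_fdt(ds)
        assert model.root.is_leaf

    def test_invalid_pruning_parameters(self, toy_fuzzy_dataset):
        with pytest.raises(ValueError):
            induct_fdt(toy_fuzzy_dataset, alpha=-0.1)
        with pytest.raises(ValueError):
            induct_fdt(toy_fuzzy_dataset, beta=1.5)

    def test_no_attribute_repeats_on_paths(self, toy_fuzzy_dataset):
        model = induct_fdt(toy_fuzzy_dataset, alpha=0.0, beta=1.0)

        def walk(node, seen):
            if node.is_leaf:
                return
            assert node.attribute_index not in seen
            for c in node.children:
                walk(c, seen | {node.attribute_index})

        walk(model.root, set())

    def test_size_monotone_in_alpha_and_beta(self):
        ds = gen_expert_dataset(SynthConfig(archetype="expert", seed=5))
        sizes_a = [
            induct_fdt(ds, alpha=a, beta=1.0).count_nodes()
            for a in (0.0, 0.02, 0.05, 0.1, 0.3, 1.0)
        ]
        assert all(x >= y for x, y in zip(sizes_a, sizes_a[1:]))
        sizes_b = [
            induct_fdt(ds, alpha=0.0, beta=b).count_nodes()
            for b in (0.0, 0.4, 0.6, 0.8, 0.95, 1.0)
        ]
        assert all(x <= y for x, y in zip(sizes_b, sizes_b[1:]))


class TestInference:
    def test_single_leaf_constant_output(self, toy_fuzzy_dataset):
        model = induct_fdt(toy_fuzzy_dataset, alpha=1.0, beta=1.0)
        conf = model.root.confidence
        for _ in range(3):
            inst = [np.random.default_rng(1).dirichlet((1, 1)) for _ in range(2)]
            np.testing.assert_allclose(fdt_classify(model, inst), conf, atol=1e-12)

    def test_crisp_instance_follows_single_path(self):
        func = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 1}  # OR
        model = induct_fdt(crisp_boolean_dataset(func), alpha=0.0, beta=1.0)
        conf = fdt_classify(model, [np.array([1.0, 0.0]), np.array([1.0, 0.0])])
        np.testing.assert_allclose(conf, [1.0, 0.0], atol=1e-12)

    def test_fuzzy_instance_blends_leaves(self):
        # depth-1 tree on attribute A1: leaves are the class distributions per term
        func = {(0, 0): 0, (0, 1): 0, (1, 0): 1, (1, 1): 1}  # f = a1
        model = induct_fdt(crisp_boolean_dataset(func), alpha=0.0, beta=1.0)
        assert model.root.attribute_index == 0 and model.root.depth() == 1
        leaf0 = model.root.children[0].confidence
        leaf1 = model.root.children[1].confidence
        conf = fdt_classify(model, [np.array([0.4, 0.6]), np.array([0.5, 0.5])])
        expected = 0.4 * leaf0 + 0.6 * leaf1
        np.testing.assert_allclose(conf, expected / expected.sum(), atol=1e-12)

    def test_confidence_sums_to_one(self, toy_fuzzy_dataset):
        model = induct_fdt(toy_fuzzy_dataset, alpha=0.0, beta=1.0)
        rng = np.random.default_rng(8)
        for _ in range(20):
            inst = [rng.dirichlet((1, 1)), rng.dirichlet((1, 1))]
            assert fdt_classify(model, inst).sum() == pytest.approx(1.0, abs=1e-9)

    def test_wrong_arity_rejected(self, toy_fuzzy_dataset):
        model = induct_fdt(toy_fuzzy_dataset)
        with pytest.raises(ValueError):
            fdt_classify(model, [np.array([1.0, 0.0, 0.0]), np.array([1.0, 0.0])])


class TestDecisionTable:
    def test_expert_structure_has_sixteen_rows(self):
        ds = gen_expert_dataset(SynthConfig(archetype="expert", seed=0))
        model = induct_fdt(ds, alpha=0.0, beta=1.0)
        table = fdt_decision_table(model)
        assert len(table) == 16  # 2 * 2 * 4 input-term combinations

    def test_single_binary_attribute_two_rows(self):
        ds = FuzzyDataset(
            attributes=[
                FuzzyAttribute("A", ("l", "h"), "input"),
                FuzzyAttribute("B", ("x", "y"), "output"),
            ],
            memberships=[np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([[1.0, 0.0], [0.0, 1.0]])],
        )
        table = fdt_decision_table(induct_fdt(ds, alpha=0.0, beta=1.0))
        assert len(table) == 2

    def test_rows_agree_with_classify(self):
        ds = gen_expert_dataset(SynthConfig(archetype="expert", seed=2))
        model = induct_fdt(ds, alpha=0.0, beta=1.0)
        table = fdt_decision_table(model)
        inputs = [i for i, a in enumerate(model.attributes) if a.role == "input"]
        for _, row in table.iterrows():
            inst = []
            for i in inputs:
                attr = model.attributes[i]
                v = np.zeros(attr.n_terms)
                v[attr.term_labels.index(row[attr.name])] = 1.0
                inst.append(v)
            assert fdt_predict_class(model, inst) == row["prediction"]


class TestExports:
    def test_rules_and_dot(self, toy_fuzzy_dataset):
        model = induct_fdt(toy_fuzzy_dataset, alpha=0.0, beta=1.0)
        rules = fdt_rules(model)
        assert rules and all(r.startswith("IF ") and " THEN class " in r for r in rules)
        dot = fdt_to_dot(model)
        assert dot.startswith("digraph") and dot.rstrip().endswith("}")


class TestFuzzyNaiveBayes:
    def test_single_crisp_sample_predicts_itself(self):
        ds = FuzzyDataset(
            attributes=[
                FuzzyAttribute("A", ("l", "h"), "input"),
                FuzzyAttribute("B", ("x", "y"), "output"),
            ],
            memberships=[np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])],
        )
        model = fnb_fit(ds, smoothing=0.0)
        conf = fnb_classify(model, [np.array([1.0, 0.0])])
        np.testing.assert_allclose(conf, [0.0, 1.0], atol=1e-12)

    def test_uninformative_attribute_posterior_equals_prior(self):
        # attribute identical across classes
        a = np.tile([0.5, 0.5], (4, 1))
        y = np.array([[1, 0], [1, 0], [1, 0], [0, 1]], float)
        ds = FuzzyDataset(
            attributes=[
                FuzzyAttribute("A", ("l", "h"), "input"),
                FuzzyAttribute("B", ("x", "y"), "output"),
            ],
            memberships=[a, y],
        )
        model = fnb_fit(ds, smoothing=0.0)
        conf = fnb_classify(model, [np.array([0.5, 0.5])])
        np.testing.assert_allclose(conf, model.priors, atol=1e-12)

    def test_crisp_counting_posterior(self):
        # 4 crisp rows; hand-computed product-rule posterior, smoothing 0
        a1 = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], float)
        a2 = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], float)
        y = np.array([[1, 0], [1, 0], [1, 0], [0, 1]], float)
        ds = FuzzyDataset(
            attributes=[
                FuzzyAttribute("A1", ("f", "t"), "input"),
                FuzzyAttribute("A2", ("f", "t"), "input"),
                FuzzyAttribute("B", ("c0", "c1"), "output"),
            ],
            memberships=[a1, a2, y],
        )
        model = fnb_fit(ds, smoothing=0.0)
        # instance (a1=t, a2=t): P(c0) ~ 3/4 * 1/3 * 1/3; P(c1) ~ 1/4 * 1 * 1
        conf = fnb_classify(model, [np.array([0.0, 1.0]), np.array([0.0, 1.0])])
        expected = np.array([0.75 * (1 / 3) * (1 / 3), 0.25 * 1.0 * 1.0])
        np.testing.assert_allclose(conf, expected / expected.sum(), atol=1e-12)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        a1 = rng.dirichlet((1, 1, 1), size=8)
        a2 = rng.dirichlet((1, 1), size=8)
        y = rng.dirichlet((1, 1), size=8)
        ds = FuzzyDataset(
            attributes=[
                FuzzyAttribute("A1", ("a", "b", "c"), "input"),
                FuzzyAttribute("A2", ("l", "h"), "input"),
                FuzzyAttribute("B", ("x", "y"), "output"),
            ],
            memberships=[a1, a2, y],
        )
        model = fnb_fit(ds, smoothing=1.0)
        inst = [rng.dirichlet((1, 1, 1)), rng.dirichlet((1, 1))]
        conf = fnb_classify(model, inst)
        # independent evaluation of the expectation-combination formula
        post = model.priors.copy()
        for pos, i in enumerate([0, 1]):
            post = post * (inst[pos] @ model.conditionals[i])
        np.testing.assert_allclose(conf, post / post.sum(), atol=1e-12)

    def test_empty_dataset_rejected(self):
        with pytest.raises((ValueError, IndexError)):
            fnb_fit(
                FuzzyDataset(
                    attributes=[
                        FuzzyAttribute("A", ("l", "h"), "input"),
                        FuzzyAttribute("B", ("x", "y"), "output"),
                    ],
                    memberships=[np.zeros((1, 2)), np.zeros((1, 2))],
                )
            )

    def test_predict_class_tie_breaks_low_index(self):
        ds = gen_expert_dataset(SynthConfig(archetype="expert", seed=3))
        model = fnb_fit(ds)
        rows = [[ds.memberships[i][r] for i in ds.input_indices] for r in range(ds.n_samples)]
        for row in rows:
            conf = fnb_classify(model, row)
            assert fnb_predict_class(model, row) == model.classes[int(np.argmax(conf))]
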