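"""Gain-ratio tree: split choice vs exhaustive oracle, rules, ranking."""

import math
from collections import Counter

import numpy as np
import pytest

from eegdem.matrix import assemble_matrix
from eegdem.tree import (
    DecisionTree,
    Node,
    best_split,
    export_rules,
    infogain_rank,
    parse_rules,
    predict,
    predict_matrix,
    train_c45,
)


def entropy(labels):
    n = len(labels)
    return -sum((c / n) * math.log2(c / n) for c in Counter(labels).values())


def oracle_best_gain_ratio(X, y, min_leaf):
    """Exhaustive enumeration of every (feature, midpoint) candidate."""
    n, F = X.shape
    best = None
    for f in range(F):
        values = np.unique(X[:, f])
        for lo, hi in zip(values, values[1:]):
            thr = (lo + hi) / 2
            mask = X[:, f] <= thr
            nl, nr = mask.sum(), (~mask).sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            gain = entropy(list(y)) - (nl / n) * entropy(list(y[mask])) \
                - (nr / n) * entropy(list(y[~mask]))
            if gain <= 1e-12:
                continue
            si = -(nl / n) * math.log2(nl / n) - (nr / n) * math.log2(nr / n)
            ratio = gain / si
            if best is None or ratio > best:
                best = ratio
    return best


def matrix_from_arrays(X, y, names=None):
    return assemble_matrix(list(X), [str(l) for l in y],
                           feature_names=names)


class TestBestSplit:
    def test_matches_exhaustive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(99)
        for trial in range(20):
            n = int(rng.integers(10, 51))
            F = int(rng.integers(2, 11))
            X = np.round(rng.standard_normal((n, F)), 2)
            y = rng.integers(0, rng.integers(2, 4), size=n)
            found = best_split(X, y, int(y.max()) + 1, min_leaf=2)
            expected = oracle_best_gain_ratio(X, y, min_leaf=2)
            if expected is None:
                assert found is None
            else:
                assert found is not None
                assert found[2] == pytest.approx(expected, abs=1e-10)

    def test_xor_has_no_positive_gain_split(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        assert best_split(X, y, 2, min_leaf=1) is None
        assert oracle_best_gain_ratio(X, y, min_leaf=1) is None


class TestTrainC45:
    def test_perfectly_separable_single_feature(self):
        X = np.array([[0.1], [0.2], [0.3], [5.1], [5.2], [5.3]])
        fm = matrix_from_arrays(X, ["A", "A", "A", "B", "B", "B"])
        tree = train_c45(fm)
        assert tree.size == 3
        assert tree.n_leaves == 2
        assert all(leaf.n_misclassified == 0 for leaf in tree.leaves())

    def test_single_class_gives_single_leaf(self):
        X = np.arange(8.0).reshape(4, 2)
        fm = matrix_from_arrays(X, ["A"] * 4)
        tree = train_c45(fm)
        assert tree.size == 1
        assert tree.root.label == "A"

    def test_leaf_totals_sum_to_training_size(self, rng):
        X = rng.standard_normal((40, 5))
        y = rng.integers(0, 2, 40)
        tree = train_c45(matrix_from_arrays(X, y))
        assert sum(l.n_total for l in tree.leaves()) == 40

    def test_row_order_invariance(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.integers(0, 2, 30)
        fm = matrix_from_arrays(X, y)
        perm = rng.permutation(30)
        fm2 = matrix_from_arrays(X[perm], y[perm])
        assert export_rules(train_c45(fm)) == export_rules(train_c45(fm2))

    def test_pruned_not_larger_than_unpruned(self, rng):
        X = rng.standard_normal((60, 4))
        y = rng.integers(0, 2, 60)  # pure noise: pruning should shrink
        fm = matrix_from_arrays(X, y)
        unpruned = train_c45(fm, prune=False)
        pruned = train_c45(fm, prune=True)
        assert pruned.size <= unpruned.size

    def test_pruning_never_increases_pessimistic_error(self, rng):
        from eegdem.tree import _subtree_pessimistic
        X = rng.standard_normal((60, 4))
        y = rng.integers(0, 2, 60)
        fm = matrix_from_arrays(X, y)
        unpruned = train_c45(fm, prune=False)
        pruned = train_c45(fm, prune=True)
        assert _subtree_pessimistic(pruned.root, 0.25) <= \
            _subtree_pessimistic(unpruned.root, 0.25) + 1e-9

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            train_c45(matrix_from_arrays(np.zeros((0, 2)), []))

    def test_json_round_trip(self, rng):
        X = rng.standard_normal((25, 3))
        y = rng.integers(0, 2, 25)
        fm = matrix_from_arrays(X, y)
        tree = train_c45(fm)
        back = DecisionTree.from_json(tree.to_json())
        assert predict_matrix(back, fm) == predict_matrix(tree, fm)


class TestPredict:
    def test_training_consistency_on_unpruned_tree(self, rng):
        X = rng.standard_normal((30, 5))
        y = rng.integers(0, 2, 30)
        fm = matrix_from_arrays(X, y)
        tree = train_c45(fm, min_leaf=1, prune=False)
        assert predict_matrix(tree, fm) == [str(l) for l in y]

    def test_single_leaf_tree_predicts_its_class(self):
        tree = DecisionTree(root=Node(class_counts={"A": 4}, label="A"),
                            feature_names=["x"], classes=["A"])
        assert predict(tree, {"x": 123.0}) == "A"

    def test_boundary_value_routes_left(self):
        root = Node(class_counts={"A": 1, "B": 1}, feature="x", threshold=1.0,
                    left=Node(class_counts={"A": 1}, label="A"),
                    right=Node(class_counts={"B": 1}, label="B"))
        tree = DecisionTree(root=root, feature_names=["x"],
                            classes=["A", "B"])
        assert predict(tree, {"x": 1.0}) == "A"
        assert predict(tree, {"x": 1.0000001}) == "B"

    def test_missing_feature_rejected(self):
        root = Node(class_counts={"A": 1, "B": 1}, feature="x", threshold=0.0,
                    left=Node(class_counts={"A": 1}, label="A"),
                    right=Node(class_counts={"B": 1}, label="B"))
        tree = DecisionTree(root=root, feature_names=["x"],
                            classes=["A", "B"])
        with pytest.raises(ValueError, match="missing feature"):
            predict(tree, {"y": 1.0})


class TestRules:
    def _example_tree(self):
        """Size-7 tree with 4 leaves (3 binary splits)."""
        def leaf(lab, n, m=0):
            other = "B" if lab == "A" else "A"
            counts = {lab: n - m}
            if m:
                counts[other] = m
            return Node(class_counts=counts, label=lab)
        inner = Node(class_counts={"A": 5, "B": 5}, feature="w2",
                     threshold=0.5, left=leaf("A", 3), right=leaf("B", 2, 1))
        inner2 = Node(class_counts={"A": 3, "B": 2}, feature="w3",
                      threshold=-1.0, left=leaf("B", 4), right=leaf("A", 1))
        root = Node(class_counts={"A": 8, "B": 7}, feature="w1",
                    threshold=0.0, left=inner, right=inner2)
        return DecisionTree(root=root, feature_names=["w1", "w2", "w3"],
                            classes=["A", "B"])

    def test_one_rule_per_leaf(self):
        tree = self._example_tree()
        assert tree.size == 7 and tree.n_leaves == 4
        rules = export_rules(tree).splitlines()
        assert len(rules) == 4

    def test_annotations_include_misclassified(self):
        text = export_rules(self._example_tree())
        assert "(2/1)" in text
        assert "(3)" in text

    def test_single_leaf_unconditional_rule(self):
        tree = DecisionTree(root=Node(class_counts={"A": 9}, label="A"),
                            feature_names=[], classes=["A"])
        assert export_rules(tree) == "if true then A (9)"

    def test_round_trip_predictions(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.integers(0, 2, 40)
        fm = matrix_from_arrays(X, y, names=["a", "b", "c", "d"])
        tree = train_c45(fm)
        ruleset = parse_rules(export_rules(tree))
        for i in range(fm.n_samples):
            sample = dict(zip(fm.feature_names, fm.values[i]))
            assert ruleset.predict(sample) == predict(tree, sample)


class TestInfoGainRank:
    def test_class_copy_feature_ranked_first_with_full_entropy(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 40)
        X = np.column_stack([rng.standard_normal(40), y.astype(float)])
        fm = matrix_from_arrays(X, y, names=["noise", "copy"])
        ranked = infogain_rank(fm)
        assert ranked[0][0] == "copy"
        assert ranked[0][1] == pytest.approx(entropy(list(y)), abs=1e-12)

    def test_constant_feature_zero_gain(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = [0] * 5 + [1] * 5
        ranked = dict(infogain_rank(matrix_from_arrays(X, y,
                                                       names=["const", "v"])))
        assert ranked["const"] == 0.0

    def test_matches_direct_entropy_oracle(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.integers(0, 2, 20)
        fm = matrix_from_arrays(X, y)
        got = dict(infogain_rank(fm, n_bins=10))
        for j, name in enumerate(fm.feature_names):
            x = X[:, j]
            bins = np.minimum((10 * (x - x.min())
                               / (x.max() - x.min())).astype(int), 9)
            h = entropy([str(l) for l in y])
            cond = 0.0
            for b in set(bins):
                sel = bins == b
                cond += sel.mean() * entropy([str(l) for l in y[sel]])
            assert got[name] == pytest.approx(h - cond, abs=1e-12)

    def test_single_class_all_zero(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        ranked = infogain_rank(matrix_from_arrays(X, ["A"] * 10))
        assert all(g == 0.0 for _, g in ranked)
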