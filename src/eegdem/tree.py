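"""C4.5-style decision trees: gain-ratio splits, pessimistic pruning,
human-readable rules, and information-gain feature ranking.

This is a from-scratch implementation rather than a wrapper around a generic
CART library because the required semantics differ in ways that matter for
interpretability: splits maximize the *gain ratio* (information gain divided
by the split's intrinsic information), pruning uses the pessimistic binomial
upper bound, and every leaf carries its training instance counts so a tree
can be exported as annotated if/then rules.

Only numeric attributes are supported (all features here are real-valued
spectral coefficients). Splits are binary: left branch takes values ≤ the
threshold, right takes values > it; thresholds are midpoints between
consecutive distinct sorted feature values. Ties in gain ratio are broken by
lower feature index, then lower threshold, so training is deterministic and
invariant to row order.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .matrix import FeatureMatrix

_EPS = 1e-12


# ---------------------------------------------------------------------------
# tree structure

@dataclass
class Node:
    """Internal split node or leaf.

    A leaf has ``label`` set; an internal node has ``feature``/``threshold``
    and two children (``left`` = "≤", ``right`` = ">"). ``class_counts`` is
    the training class distribution reaching the node (used for pruning).
    """

    class_counts: dict[str, int]
    feature: str | None = None
    threshold: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    @property
    def n_total(self) -> int:
        return sum(self.class_counts.values())

    @property
    def n_misclassified(self) -> int:
        if not self.is_leaf:
            raise ValueError("instance counts are defined on leaves")
        return self.n_total - self.class_counts.get(self.label, 0)

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"label": self.label, "counts": self.class_counts}
        return {"feature": self.feature, "threshold": self.threshold,
                "counts": self.class_counts,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "Node":
        if "label" in d:
            return cls(class_counts=dict(d["counts"]), label=d["label"])
        return cls(class_counts=dict(d["counts"]), feature=d["feature"],
                   threshold=float(d["threshold"]),
                   left=cls.from_dict(d["left"]),
                   right=cls.from_dict(d["right"]))


@dataclass
class DecisionTree:
    """Trained gain-ratio decision tree over named numeric features."""

    root: Node
    feature_names: list[str]
    classes: list[str]

    @property
    def size(self) -> int:
        def count(n: Node) -> int:
            return 1 if n.is_leaf else 1 + count(n.left) + count(n.right)
        return count(self.root)

    @property
    def n_leaves(self) -> int:
        def count(n: Node) -> int:
            return 1 if n.is_leaf else count(n.left) + count(n.right)
        return count(self.root)

    def leaves(self) -> list[Node]:
        out: list[Node] = []

        def walk(n: Node) -> None:
            if n.is_leaf:
                out.append(n)
            else:
                walk(n.left)
                walk(n.right)
        walk(self.root)
        return out

    def to_json(self) -> str:
        return json.dumps({"classes": self.classes,
                           "feature_names": self.feature_names,
                           "root": self.root.to_dict()}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        d = json.loads(text)
        return cls(root=Node.from_dict(d["root"]),
                   feature_names=list(d["feature_names"]),
                   classes=list(d["classes"]))


# ---------------------------------------------------------------------------
# entropy helpers

def _entropy_from_counts(counts: np.ndarray, axis: int = 0) -> np.ndarray:
    """Shannon entropy (bits) of count vectors along ``axis``; 0·log0 = 0."""
    total = counts.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, counts / np.maximum(total, 1), 0.0)
        term = np.where(p > 0, p * np.log2(p), 0.0)
    return -term.sum(axis=axis)


def best_split(X: np.ndarray, y: np.ndarray, n_classes: int,
               min_leaf: int) -> tuple[int, float, float] | None:
    """Exhaustive gain-ratio maximization over (feature, midpoint) candidates.

    Returns ``(feature_index, threshold, gain_ratio)`` or ``None`` when no
    candidate satisfies the min_leaf constraint with positive gain. Ties are
    broken by lower feature index, then lower threshold.
    """
    n, F = X.shape
    if n < 2 * min_leaf:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    ys = y[order]                                    # (n, F)
    onehot = np.zeros((n_classes, n, F))
    for c in range(n_classes):
        onehot[c] = np.cumsum(ys == c, axis=0)
    left = onehot[:, :-1, :]                         # counts left of cut i
    total = onehot[:, -1:, :]                        # per-feature totals
    right = total - left

    nl = np.arange(1, n, dtype=float)[:, None]       # (n-1, 1)
    nr = n - nl
    h_left = _entropy_from_counts(left, axis=0)
    h_right = _entropy_from_counts(right, axis=0)
    parent_counts = np.bincount(y, minlength=n_classes).astype(float)
    h_parent = _entropy_from_counts(parent_counts)
    gain = h_parent - (nl / n) * h_left - (nr / n) * h_right
    split_info = -(nl / n) * np.log2(nl / n) - (nr / n) * np.log2(nr / n)

    valid = (Xs[:-1] < Xs[1:]) & (nl >= min_leaf) & (nr >= min_leaf) \
        & (gain > _EPS)
    ratio = np.where(valid, gain / split_info, -np.inf)
    if not valid.any():
        return None
    # feature-major flattening => argmax ties resolve to lower feature index,
    # then lower threshold (positions ascend with value within a feature)
    flat = ratio.T.ravel()
    idx = int(np.argmax(flat))
    f, pos = divmod(idx, n - 1)
    threshold = float((Xs[pos, f] + Xs[pos + 1, f]) / 2.0)
    return f, threshold, float(flat[idx])


# ---------------------------------------------------------------------------
# training

def _counts_dict(y: np.ndarray, classes: Sequence[str]) -> dict[str, int]:
    bc = np.bincount(y, minlength=len(classes))
    return {c: int(bc[i]) for i, c in enumerate(classes)}


def _majority(y: np.ndarray, classes: Sequence[str]) -> str:
    bc = np.bincount(y, minlength=len(classes))
    return classes[int(np.argmax(bc))]  # ties -> lowest class index


def _grow(X: np.ndarray, y: np.ndarray, classes: Sequence[str],
          feature_names: Sequence[str], min_leaf: int) -> Node:
    counts = _counts_dict(y, classes)
    if len(np.unique(y)) == 1:
        return Node(class_counts=counts, label=classes[int(y[0])])
    found = best_split(X, y, len(classes), min_leaf)
    if found is None:
        return Node(class_counts=counts, label=_majority(y, classes))
    f, thr, _ = found
    mask = X[:, f] <= thr
    node = Node(class_counts=counts, feature=feature_names[f], threshold=thr)
    node.left = _grow(X[mask], y[mask], classes, feature_names, min_leaf)
    node.right = _grow(X[~mask], y[~mask], classes, feature_names, min_leaf)
    return node


def pessimistic_errors(e: int, n: int, cf: float) -> float:
    """C4.5 upper-bound error estimate: n times the binomial upper limit.

    Uses the normal-approximation (Wilson) upper confidence bound at level
    ``cf``; the error-free case uses the exact bound 1 − cf^(1/n).
    """
    if n == 0:
        return 0.0
    if e == 0:
        return n * (1.0 - cf ** (1.0 / n))
    z = float(norm.ppf(1.0 - cf))
    f = e / n
    u = (f + z * z / (2 * n)
         + z * math.sqrt(f / n - f * f / n + z * z / (4 * n * n))) \
        / (1.0 + z * z / n)
    return n * min(1.0, u)


def _subtree_pessimistic(node: Node, cf: float) -> float:
    if node.is_leaf:
        return pessimistic_errors(node.n_misclassified, node.n_total, cf)
    return (_subtree_pessimistic(node.left, cf)
            + _subtree_pessimistic(node.right, cf))


def _prune(node: Node, classes: Sequence[str], cf: float) -> Node:
    """Bottom-up pessimistic pruning (no subtree raising)."""
    if node.is_leaf:
        return node
    node.left = _prune(node.left, classes, cf)
    node.right = _prune(node.right, classes, cf)
    n = node.n_total
    best_label = max(classes, key=lambda c: node.class_counts.get(c, 0))
    e_leaf = n - node.class_counts.get(best_label, 0)
    as_leaf = pessimistic_errors(e_leaf, n, cf)
    as_subtree = _subtree_pessimistic(node, cf)
    if as_leaf <= as_subtree + 1e-9:
        return Node(class_counts=dict(node.class_counts), label=best_label)
    return node


def train_c45(matrix: FeatureMatrix, min_leaf: int = 2,
              cf: float = 0.25, prune: bool = True) -> DecisionTree:
    """Grow and prune a gain-ratio decision tree on a feature matrix.

    Parameters mirror the common J48 defaults: ``min_leaf`` is the minimum
    number of training instances per branch of an accepted split, ``cf`` the
    pruning confidence (smaller prunes harder). Training is deterministic.
    """
    if matrix.n_samples == 0:
        raise ValueError("empty feature matrix")
    classes = matrix.classes
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[l] for l in matrix.labels])
    root = _grow(matrix.values, y, classes, matrix.feature_names, min_leaf)
    if prune:
        root = _prune(root, classes, cf)
    return DecisionTree(root=root, feature_names=list(matrix.feature_names),
                        classes=classes)


# ---------------------------------------------------------------------------
# prediction

def _as_mapping(sample, feature_names: Sequence[str]) -> Mapping[str, float]:
    if isinstance(sample, Mapping):
        return sample
    arr = np.asarray(sample, dtype=float)
    if arr.shape != (len(feature_names),):
        raise ValueError("sample length does not match the tree's features")
    return dict(zip(feature_names, arr))


def predict(tree: DecisionTree, sample) -> str:
    """Route one sample (mapping or vector in tree feature order) to a leaf.

    Values exactly equal to a threshold go left (the "≤" branch).
    """
    values = _as_mapping(sample, tree.feature_names)
    node = tree.root
    while not node.is_leaf:
        if node.feature not in values:
            raise ValueError(f"sample is missing feature {node.feature!r}")
        node = node.left if values[node.feature] <= node.threshold else node.right
    return node.label


def predict_matrix(tree: DecisionTree, matrix: FeatureMatrix) -> list[str]:
    index = {n: i for i, n in enumerate(matrix.feature_names)}
    cols = [index[f] for f in tree.feature_names]
    return [predict(tree, matrix.values[i, cols])
            for i in range(matrix.n_samples)]


# ---------------------------------------------------------------------------
# rule export / import

def export_rules(tree: DecisionTree) -> str:
    """One ``if … then CLASS (n/m)`` rule per leaf (root-to-leaf conjunction).

    The misclassification count ``m`` is omitted when zero, matching the
    usual J48 annotation. Thresholds are printed at full precision so the
    rules re-parse to an exactly equivalent classifier.
    """
    lines: list[str] = []

    def walk(node: Node, path: list[str]) -> None:
        if node.is_leaf:
            ann = (f"({node.n_total}/{node.n_misclassified})"
                   if node.n_misclassified else f"({node.n_total})")
            cond = " and ".join(path) if path else "true"
            lines.append(f"if {cond} then {node.label} {ann}")
            return
        walk(node.left, path + [f"{node.feature} <= {node.threshold!r}"])
        walk(node.right, path + [f"{node.feature} > {node.threshold!r}"])

    walk(tree.root, [])
    return "\n".join(lines)


_RULE_RE = re.compile(
    r"^if (?P<cond>.+) then (?P<label>\S+) \((?P<n>\d+)(?:/(?P<m>\d+))?\)$")
_PRED_RE = re.compile(r"^(?P<feat>\S+) (?P<op><=|>) (?P<val>\S+)$")


@dataclass
class Rule:
    predicates: list[tuple[str, str, float]]
    label: str
    n_total: int
    n_misclassified: int

    def matches(self, values: Mapping[str, float]) -> bool:
        for feat, op, val in self.predicates:
            if feat not in values:
                raise ValueError(f"sample is missing feature {feat!r}")
            ok = values[feat] <= val if op == "<=" else values[feat] > val
            if not ok:
                return False
        return True


@dataclass
class RuleSet:
    """Parsed rule list; equivalent to the tree it was exported from."""

    rules: list[Rule] = field(default_factory=list)

    def predict(self, sample, feature_names: Sequence[str] | None = None) -> str:
        if not isinstance(sample, Mapping):
            if feature_names is None:
                raise ValueError("feature_names required for vector input")
            sample = dict(zip(feature_names, np.asarray(sample, dtype=float)))
        for rule in self.rules:
            if rule.matches(sample):
                return rule.label
        raise ValueError("no rule matched (rule set is not exhaustive)")


def parse_rules(text: str) -> RuleSet:
    rules: list[Rule] = []
    for line in filter(None, (l.strip() for l in text.splitlines())):
        m = _RULE_RE.match(line)
        if m is None:
            raise ValueError(f"unparseable rule: {line!r}")
        preds: list[tuple[str, str, float]] = []
        if m["cond"] != "true":
            for clause in m["cond"].split(" and "):
                p = _PRED_RE.match(clause.strip())
                if p is None:
                    raise ValueError(f"unparseable predicate: {clause!r}")
                preds.append((p["feat"], p["op"], float(p["val"])))
        rules.append(Rule(predicates=preds, label=m["label"],
                          n_total=int(m["n"]),
                          n_misclassified=int(m["m"] or 0)))
    return RuleSet(rules=rules)


# ---------------------------------------------------------------------------
# information-gain ranking

def infogain_rank(matrix: FeatureMatrix,
                  n_bins: int = 10) -> list[tuple[str, float]]:
    """Rank features by information gain after equal-width discretization.

    Each feature is cut into ``n_bins`` equal-width bins over its observed
    range (a constant feature yields one bin, hence zero gain); the gain is
    H(class) − H(class | bin). The returned list is sorted by descending
    gain with ties broken by ascending feature index.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    classes = matrix.classes
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[l] for l in matrix.labels])
    n = y.size
    h_class = _entropy_from_counts(
        np.bincount(y, minlength=len(classes)).astype(float))

    gains: list[tuple[str, float]] = []
    for j, name in enumerate(matrix.feature_names):
        x = matrix.values[:, j]
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            gains.append((name, 0.0))
            continue
        bins = np.minimum((n_bins * (x - lo) / (hi - lo)).astype(int),
                          n_bins - 1)
        h_cond = 0.0
        for b in np.unique(bins):
            sel = bins == b
            h_cond += (sel.sum() / n) * float(_entropy_from_counts(
                np.bincount(y[sel], minlength=len(classes)).astype(float)))
        gains.append((name, float(h_class - h_cond)))
    order = sorted(range(len(gains)), key=lambda j: (-gains[j][1], j))
    return [gains[j] for j in order]
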