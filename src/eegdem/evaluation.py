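"""Binary classification problems, cross-validation and permutation control.

Four two-class problems are built from the three diagnostic groups: HC vs AD,
HC vs MCI, MCI vs AD, and HC vs CASE where CASE pools MCI and AD (diseased vs
healthy). Evaluation pools per-fold predictions into a single confusion
matrix and reports accuracy, precision, sensitivity (recall), specificity
and F-measure as percentages. Precision/sensitivity/F-measure/specificity
are support-weighted averages across the two classes (per-class values are
kept alongside); with this weighting, sensitivity coincides with accuracy.

The permutation control refits the whole cross-validation under randomly
shuffled class labels: a model family that only memorizes noise will score
similarly with real and shuffled labels, whereas a genuine class signal
shows up as the real-label accuracy exceeding the permutation distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .matrix import FeatureMatrix
from .tree import DecisionTree, infogain_rank, predict_matrix, train_c45

logger = logging.getLogger(__name__)

PROBLEMS = {
    "HCvsAD": ("HC", "AD"),
    "HCvsMCI": ("HC", "MCI"),
    "MCIvsAD": ("MCI", "AD"),
    "HCvsCASE": ("HC", "CASE"),
}
SCHEMES = ("loocv", "kfold10", "holdout90")


@dataclass
class EvaluationReport:
    """Pooled cross-validation result for one binary problem."""

    problem: str
    scheme: str
    n_folds: int
    class_labels: list[str]
    confusion: np.ndarray = field(repr=False)  # rows true, cols predicted
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    accuracy: float = 0.0
    precision: float = 0.0
    sensitivity: float = 0.0
    specificity: float = 0.0
    f_measure: float = 0.0

    def to_dict(self) -> dict:
        return {
            "problem": self.problem, "scheme": self.scheme,
            "n_folds": self.n_folds, "class_labels": self.class_labels,
            "confusion": np.asarray(self.confusion).astype(int).tolist(),
            "per_class": self.per_class,
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f_measure": self.f_measure,
        }

    def summary(self) -> str:
        """Render the five weighted metrics as an aligned text table."""
        rows = [("Accuracy", self.accuracy), ("Precision", self.precision),
                ("Sensitivity", self.sensitivity),
                ("Specificity", self.specificity),
                ("F-measure", self.f_measure)]
        head = (f"{self.problem} [{self.scheme}, {self.n_folds} folds] "
                f"classes={'/'.join(self.class_labels)}")
        body = "\n".join(f"  {name:<12}{value:6.1f} %" for name, value in rows)
        return head + "\n" + body


def make_problem(matrix: FeatureMatrix, problem: str) -> FeatureMatrix:
    """Reduce the 3-class matrix to one of the four binary problems."""
    if problem not in PROBLEMS:
        raise ValueError(f"unknown problem {problem!r}; "
                         f"expected one of {sorted(PROBLEMS)}")
    a, b = PROBLEMS[problem]
    m = matrix.relabel({"MCI": "CASE", "AD": "CASE"}) \
        if problem == "HCvsCASE" else matrix
    rows = [i for i, l in enumerate(m.labels) if l in (a, b)]
    present = {m.labels[i] for i in rows}
    missing = {a, b} - present
    if missing:
        raise ValueError(f"class(es) {sorted(missing)} absent from matrix")
    return m.select(rows=rows)


def metrics_from_confusion(confusion: np.ndarray,
                           class_labels: list[str]) -> dict:
    """Five-metric summary (percent) from a pooled confusion matrix.

    Rows are true classes, columns predicted, both in ``class_labels`` order.
    Precision/recall/F/specificity are computed per class and averaged with
    class-support weights. In the binary case the specificity of one class is
    the recall of the other.
    """
    conf = np.asarray(confusion, dtype=float)
    n = conf.sum()
    support = conf.sum(axis=1)
    per_class: dict[str, dict[str, float]] = {}
    weighted = {"precision": 0.0, "sensitivity": 0.0,
                "specificity": 0.0, "f_measure": 0.0}
    for i, lab in enumerate(class_labels):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = support[i] - tp
        tn = n - tp - fp - fn
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        spec = tn / (tn + fp) if tn + fp > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        per_class[lab] = {"precision": 100 * prec, "sensitivity": 100 * rec,
                          "specificity": 100 * spec, "f_measure": 100 * f1}
        w = support[i] / n if n > 0 else 0.0
        weighted["precision"] += w * prec
        weighted["sensitivity"] += w * rec
        weighted["specificity"] += w * spec
        weighted["f_measure"] += w * f1
    accuracy = float(np.trace(conf) / n) if n > 0 else 0.0
    return {"accuracy": 100 * accuracy, "per_class": per_class,
            **{k: 100 * v for k, v in weighted.items()}}


def _folds(labels: list[str], scheme: str, seed: int):
    """Yield (train_idx, test_idx) pairs for the chosen sampling scheme."""
    y = np.asarray(labels)
    idx = np.arange(y.size)
    if scheme == "loocv":
        for i in idx:
            yield np.delete(idx, i), np.array([i])
    elif scheme == "kfold10":
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("each class needs >= 2 samples for k-fold")
        k = min(10, int(counts.min()))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        yield from skf.split(idx[:, None], y)
    elif scheme == "holdout90":
        sss = StratifiedShuffleSplit(n_splits=1, test_size=0.1,
                                     random_state=seed)
        yield from sss.split(idx[:, None], y)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; "
                         f"expected one of {SCHEMES}")


def cross_validate(matrix: FeatureMatrix, scheme: str = "loocv",
                   seed: int = 0, min_leaf: int = 2, cf: float = 0.25,
                   problem: str = "custom",
                   top_k: int | None = None) -> EvaluationReport:
    """Cross-validate a gain-ratio tree; pool predictions, compute metrics.

    With ``top_k`` set, information-gain feature selection runs inside each
    training fold (the held-out rows never influence the ranking) and the
    tree is trained on the selected columns only.
    """
    classes = matrix.classes
    if len(classes) != 2:
        raise ValueError("binary problem expected")
    if any(matrix.labels.count(c) < 2 for c in classes):
        raise ValueError("each class needs at least 2 samples")
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        if top_k > matrix.n_features:
            logger.warning("top_k=%d exceeds feature count %d; capped",
                           top_k, matrix.n_features)
            top_k = matrix.n_features

    cindex = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((2, 2), dtype=int)
    n_folds = 0
    for train_idx, test_idx in _folds(matrix.labels, scheme, seed):
        n_folds += 1
        train = matrix.select(rows=train_idx)
        if top_k is not None:
            chosen = {name for name, _ in infogain_rank(train)[:top_k]}
            # keep original column order so top_k = n_features is an identity
            selected = [n for n in train.feature_names if n in chosen]
            train = train.select(columns=selected)
        tree = train_c45(train, min_leaf=min_leaf, cf=cf)
        test = matrix.select(rows=test_idx)
        for true, pred in zip(test.labels, predict_matrix(tree, test)):
            confusion[cindex[true], cindex[pred]] += 1

    stats = metrics_from_confusion(confusion, classes)
    return EvaluationReport(
        problem=problem, scheme=scheme, n_folds=n_folds,
        class_labels=classes, confusion=confusion,
        per_class=stats["per_class"], accuracy=stats["accuracy"],
        precision=stats["precision"], sensitivity=stats["sensitivity"],
        specificity=stats["specificity"], f_measure=stats["f_measure"])


def select_then_validate(matrix: FeatureMatrix, scheme: str = "loocv",
                         seed: int = 0, top_k: int = 10,
                         **kwargs) -> EvaluationReport:
    """Cross-validation with fold-nested information-gain selection."""
    return cross_validate(matrix, scheme=scheme, seed=seed, top_k=top_k,
                          **kwargs)


def permutation_test(matrix: FeatureMatrix, n_perm: int = 100,
                     scheme: str = "loocv", seed: int = 0,
                     **kwargs) -> tuple[np.ndarray, float]:
    """Label-shuffle control: accuracy distribution under permuted classes.

    Each permutation shuffles the label column only (class sizes preserved),
    reruns the full cross-validation, and records the pooled accuracy.
    Returns the per-permutation accuracies (percent) and their mean.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.asarray(matrix.labels)
    accs = np.empty(n_perm)
    for p in range(n_perm):
        shuffled = rng.permutation(labels).tolist()
        perm = FeatureMatrix(feature_names=list(matrix.feature_names),
                             values=matrix.values, labels=shuffled,
                             sample_ids=list(matrix.sample_ids))
        report = cross_validate(perm, scheme=scheme, seed=seed, **kwargs)
        accs[p] = report.accuracy
    return accs, float(accs.mean())
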