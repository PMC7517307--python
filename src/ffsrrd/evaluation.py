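"""Classification-performance harness: repeated stratified k-fold CV.

Evaluates a fixed feature subset with pluggable classifiers under repeated
stratified 10-fold cross-validation, reporting accuracy, F-measure (beta=1)
and AUC. Selection happens upstream by default (the subset is fixed before
folding); an optional per-fold re-selection mode is available for
leakage-free analysis. Multi-class F-measure and AUC are macro-averaged.

Classifiers are any objects following the scikit-learn fit/predict contract;
:func:`default_classifiers` supplies Naive Bayes, SVM, 3-nearest-neighbours
and a decision tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data_model import Dataset
from .selectors import median_threshold

__all__ = [
    "EvaluationConfig",
    "EvaluationReport",
    "default_classifiers",
    "truncate_subset",
    "evaluate_selection",
]

METRICS = ("accuracy", "f_measure", "auc")


def default_classifiers() -> dict[str, object]:
    """The four standard classifiers used throughout, as sklearn estimators."""
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "NB": GaussianNB(),
        "SVM": SVC(probability=True, random_state=0),
        "KNN": KNeighborsClassifier(n_neighbors=3),
        "DT": DecisionTreeClassifier(random_state=0),
    }


@dataclass
class EvaluationConfig:
    folds: int = 10
    repeats: int = 10
    metrics: tuple[str, ...] = METRICS
    classifiers: Mapping[str, object] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        bad = set(self.metrics) - set(METRICS)
        if bad:
            raise ValueError(f"unknown metrics {sorted(bad)}")


@dataclass
class EvaluationReport:
    """Mean scores plus per-fold raw scores, per classifier and metric."""

    means: dict[str, dict[str, float]]
    raw: dict[str, dict[str, list[float]]]
    selected: tuple[int, ...]

    def to_tsv(self) -> str:
        lines = ["classifier\tmetric\tmean\tsd"]
        for clf, metrics in self.means.items():
            for metric, mean in metrics.items():
                sd = float(np.std(self.raw[clf][metric]))
                lines.append(f"{clf}\t{metric}\t{mean:.4f}\t{sd:.4f}")
        return "\n".join(lines)


def truncate_subset(order: Sequence[int], n: int, k: int | None = None) -> tuple[int, ...]:
    """Apply the median-threshold truncation rule to a (possibly short) ranking.

    Rankings longer than the threshold are cut to their first ``k`` entries;
    shorter subsets (e.g. from the greedy dependency search) pass unchanged.
    """
    if k is None:
        k = median_threshold(n)
    order = tuple(int(f) for f in order)
    return order[:k] if len(order) > k else order


def _scores(y_true, y_pred, proba, classes, metric: str) -> float:
    if metric == "accuracy":
        return float(accuracy_score(y_true, y_pred))
    if metric == "f_measure":
        avg = "binary" if len(classes) == 2 else "macro"
        pos = classes[1] if len(classes) == 2 else None
        return float(f1_score(y_true, y_pred, average=avg, pos_label=pos,
                              zero_division=0))
    if metric == "auc":
        present = np.unique(y_true)
        if len(classes) == 2:
            if len(present) < 2:
                return 0.5  # degenerate fold: chance-level by convention
            return float(roc_auc_score(y_true, proba[:, 1]))
        try:
            return float(
                roc_auc_score(y_true, proba, multi_class="ovr",
                              average="macro", labels=classes)
            )
        except ValueError:
            return 0.5
    raise ValueError(metric)


def evaluate_selection(
    dataset: Dataset,
    selected: Sequence[int],
    config: EvaluationConfig | None = None,
    reselect: Callable[[Dataset], Sequence[int]] | None = None,
) -> EvaluationReport:
    """Repeated stratified k-fold CV of classifiers on a feature subset.

    Parameters
    ----------
    selected
        Feature indices to evaluate (fixed across folds by default).
    reselect
        Optional callable re-running selection on each training fold
        (leakage-free mode); it receives the training-fold Dataset and must
        return feature indices.
    """
    if config is None:
        config = EvaluationConfig()
    selected = tuple(int(f) for f in selected)
    if len(selected) == 0:
        raise ValueError("selected subset must be non-empty")
    if any(f < 0 or f >= dataset.n for f in selected):
        raise ValueError("feature index out of range")
    classifiers = dict(config.classifiers or default_classifiers())
    classes = np.unique(dataset.y)
    X, y = dataset.X, dataset.y

    raw: dict[str, dict[str, list[float]]] = {
        name: {m: [] for m in config.metrics} for name in classifiers
    }
    for rep in range(config.repeats):
        skf = StratifiedKFold(
            n_splits=config.folds, shuffle=True, random_state=config.seed + rep
        )
        for train_idx, test_idx in skf.split(X, y):
            if reselect is not None:
                fold_ds = Dataset(
                    X[train_idx], y[train_idx],
                    dataset.feature_names, dataset.feature_kinds,
                )
                cols = tuple(int(f) for f in reselect(fold_ds))
            else:
                cols = selected
            Xtr, Xte = X[np.ix_(train_idx, cols)], X[np.ix_(test_idx, cols)]
            ytr, yte = y[train_idx], y[test_idx]
            for name, proto in classifiers.items():
                clf = clone(proto)
                clf.fit(Xtr, ytr)
                y_pred = clf.predict(Xte)
                proba = (
                    clf.predict_proba(Xte)
                    if hasattr(clf, "predict_proba")
                    else None
                )
                for metric in config.metrics:
                    if metric == "auc" and proba is None:
                        raise ValueError(
                            f"classifier {name!r} lacks predict_proba needed for AUC"
                        )
                    raw[name][metric].append(
                        _scores(yte, y_pred, proba, classes, metric)
                    )
    means = {
        name: {m: float(np.mean(v)) for m, v in metrics.items()}
        for name, metrics in raw.items()
    }
    return EvaluationReport(means, raw, selected)
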