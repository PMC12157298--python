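"""Posture-classifier benchmarking: grid search, held-out test, ten-fold CV.

Compares the four classifier families used for the garment's recognition
layer — k-nearest neighbours, RBF-kernel SVM, decision tree and random
forest — by exhaustive grid search over small hyperparameter grids, held-out
accuracy on a stratified 20% test partition, and stratified ten-fold
cross-validation. The selection rule picks the family with the highest CV
mean accuracy, breaking ties by the lowest CV standard deviation, mirroring
the "highest accuracy and strongest stability" criterion under which the
random forest is chosen for deployment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .postures import Posture
from .preprocess import Dataset, SplitSpec, minmax_normalize, split

N_CLASSES = len(Posture)

#: Hyperparameter names each family's grid may reference.
ALLOWED_PARAMS: dict[str, frozenset[str]] = {
    "knn": frozenset({"n_neighbors"}),
    "svm_rbf": frozenset({"C", "gamma"}),
    "decision_tree": frozenset({"max_depth", "min_samples_leaf", "min_samples_split"}),
    "random_forest": frozenset(
        {"max_depth", "min_samples_leaf", "min_samples_split", "n_estimators"}
    ),
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family plus its hyperparameter grid."""

    family: str
    grid: Mapping[str, Sequence]

    def __post_init__(self) -> None:
        if self.family not in ALLOWED_PARAMS:
            raise ValueError(f"unknown model family: {self.family!r}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid must be non-empty")
        extra = set(self.grid) - ALLOWED_PARAMS[self.family]
        if extra:
            raise ValueError(f"parameters {sorted(extra)} not valid for {self.family}")


def default_specs() -> list[ModelSpec]:
    """Default grids bracketing each family's typical optimum."""
    tree_grid = {"max_depth": [5, 10, 20, None], "min_samples_leaf": [1, 2],
                 "min_samples_split": [2, 4]}
    return [
        ModelSpec("knn", {"n_neighbors": [1, 3, 5, 7]}),
        ModelSpec("svm_rbf", {"C": [0.1, 1, 10], "gamma": [0.01, 0.1, 1]}),
        ModelSpec("decision_tree", tree_grid),
        ModelSpec("random_forest", {**tree_grid, "n_estimators": [100]}),
    ]


def make_estimator(family: str, params: Mapping | None = None, seed: int = 0):
    """Instantiate the sklearn estimator for a family with given params."""
    params = dict(params or {})
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "svm_rbf":
        return SVC(kernel="rbf", **params)  # one-vs-one multiclass (libsvm default)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model family: {family!r}")


@dataclass
class ModelReport:
    """Benchmark result for one classifier family."""

    family: str
    best_params: dict
    grid_score: float
    test_accuracy: float | None = None
    cv_mean: float | None = None
    cv_sd: float | None = None
    confusion: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "best_params": self.best_params,
            "grid_score": self.grid_score,
            "test_accuracy": self.test_accuracy,
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
        }
        if self.confusion is not None:
            d["confusion"] = self.confusion.tolist()
        return d


def _param_sort_key(params: Mapping) -> tuple:
    # lexicographic over sorted parameter names; None sorts after numbers
    key = []
    for name in sorted(params):
        v = params[name]
        key.append((name, v is None, v if isinstance(v, (int, float)) else str(v)))
    return tuple(key)


def grid_search(
    spec: ModelSpec, train: Dataset, folds: int = 5, seed: int = 0
) -> tuple[dict, float]:
    """Exhaustively evaluate the grid by stratified k-fold CV accuracy.

    Returns the best parameter point and its mean CV accuracy; ties are
    broken deterministically by lexicographic parameter order.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(train.labels)
    if counts[counts > 0].min() < folds:
        raise ValueError("fold count exceeds the smallest class size")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(
        make_estimator(spec.family, seed=seed),
        dict(spec.grid),
        scoring="accuracy",
        cv=cv,
        refit=False,
    )
    gs.fit(train.features, train.labels)
    scores = gs.cv_results_["mean_test_score"]
    candidates = gs.cv_results_["params"]
    best = max(scores)
    tied = [p for p, s in zip(candidates, scores) if s == best]
    best_params = min(tied, key=_param_sort_key)
    return dict(best_params), float(best)


def train_and_test(
    spec: ModelSpec,
    best_params: Mapping,
    train: Dataset,
    test: Dataset,
    seed: int = 0,
) -> ModelReport:
    """Fit on the training partition only; report held-out accuracy and the
    7-class confusion matrix (rows true, columns predicted)."""
    for part in (train, test):
        if part.labels.size and (part.labels.min() < 0 or part.labels.max() >= N_CLASSES):
            raise ValueError("labels must lie in 0..6")
    est = make_estimator(spec.family, best_params, seed=seed)
    est.fit(train.features, train.labels)
    pred = est.predict(test.features)
    acc = accuracy_score(test.labels, pred)
    cm = confusion_matrix(test.labels, pred, labels=list(range(N_CLASSES)))
    return ModelReport(spec.family, dict(best_params), np.nan, float(acc), confusion=cm)


def cross_validate(
    family: str,
    params: Mapping,
    data: Dataset,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified k-fold CV; returns (mean, population SD) of fold accuracies."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(data.labels)
    if counts[counts > 0].min() < k:
        raise ValueError("each class needs at least k members for stratified folds")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = cross_val_score(
        make_estimator(family, params, seed=seed),
        data.features,
        data.labels,
        scoring="accuracy",
        cv=cv,
    )
    return float(scores.mean()), float(scores.std())


def compare_models(
    specs: Sequence[ModelSpec],
    dataset: Dataset,
    *,
    split_spec: SplitSpec | None = None,
    grid_folds: int = 5,
    cv_folds: int = 10,
    seed: int = 0,
) -> tuple[list[ModelReport], str]:
    """Run the full benchmark and apply the model-selection rule.

    Pipeline: stratified 80/20 split, min–max normalization fitted on the
    training partition, per-family grid search on the training partition,
    held-out test accuracy with confusion matrix, stratified ``cv_folds``-fold
    CV on the full (normalized) dataset with the grid optimum. Families are
    ranked by highest CV mean, ties broken by lowest CV SD; the first-ranked
    family is selected.
    """
    if len(specs) < 2:
        raise ValueError("need at least two model specs to compare")
    split_spec = split_spec or SplitSpec(seed=seed)
    train, test = split(dataset, split_spec)
    train_n, (test_n, full_n), _ = minmax_normalize(
        train, [test, Dataset(dataset.features, dataset.labels)]
    )
    reports = []
    for spec in specs:
        best_params, best_score = grid_search(spec, train_n, grid_folds, seed)
        report = train_and_test(spec, best_params, train_n, test_n, seed)
        report.grid_score = best_score
        report.cv_mean, report.cv_sd = cross_validate(
            spec.family, best_params, full_n, cv_folds, seed
        )
        reports.append(report)
    order = sorted(
        range(len(reports)),
        key=lambda i: (-reports[i].cv_mean, reports[i].cv_sd, i),
    )
    ranked = [reports[i] for i in order]
    return ranked, ranked[0].family


def render_report_table(reports: Sequence[ModelReport]) -> str:
    """Plain-text benchmark table (optimal parameters, accuracies, CV stats)."""
    lines = [
        f"{'Model':<16}{'Best parameters':<48}{'Test acc':>9}{'CV mean':>9}{'CV SD':>8}"
    ]
    for r in reports:
        params = ", ".join(f"{k}={v}" for k, v in sorted(r.best_params.items()))
        cv_mean = f"{100 * r.cv_mean:.2f}%" if r.cv_mean is not None else "-"
        cv_sd = f"{100 * r.cv_sd:.2f}%" if r.cv_sd is not None else "-"
        acc = f"{100 * r.test_accuracy:.2f}%" if r.test_accuracy is not None else "-"
        lines.append(f"{r.family:<16}{params:<48}{acc:>9}{cv_mean:>9}{cv_sd:>8}")
    return "\n".join(lines)
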