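"""Disease classification under a repeated stratified k-fold protocol.

The evaluation mirrors a 15-fold cross-validation repeated 10 times: folds
are stratified so every test fold holds at least one subject of each class,
hyperparameters are tuned per fold on an inner validation split of the
training folds only, the model is refitted on the whole training set, and
metrics are pooled per repeat and reported as mean (SD) over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .core import RetoctError

ALGORITHMS = ("rf", "logistic", "svm_linear", "svm_rbf", "adaboost",
              "naive_bayes", "tree_regression", "tree_classification")

# Grids are listed in tie-break preference order: the simplest / smoothest
# model first (fewest trees, largest kernel scale).
DEFAULT_GRIDS: Dict[str, List[Dict[str, float]]] = {
    "rf": [{"n_estimators": n} for n in (50, 100, 200, 500)],
    "svm_rbf": [{"kernel_scale": s} for s in np.geomspace(10.0, 0.1, 5)],
}


@dataclass
class LabeledCohort:
    """Feature matrix with labels; optionally instrumented for access logging."""

    features: np.ndarray
    labels: np.ndarray
    ids: Optional[Sequence[str]] = None
    access_log: Optional[List[Tuple]] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise RetoctError("features must be 2D")
        if len(self.labels) != len(self.features):
            raise RetoctError("labels/features length mismatch")
        if np.isnan(self.features).any():
            raise RetoctError("features contain missing values")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray, phase: str = "") -> Tuple[np.ndarray, np.ndarray]:
        if self.access_log is not None:
            self.access_log.append((phase, tuple(int(i) for i in idx)))
        return self.features[idx], self.labels[idx]


@dataclass(frozen=True)
class Metrics:
    """Percent-scale metrics; fields are ``None`` when not applicable."""

    accuracy: float
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    f1: Optional[float] = None
    auc: Optional[float] = None
    auc_per_class: Optional[Dict[str, float]] = None

    def to_dict(self) -> Dict[str, object]:
        d = {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
             "specificity": self.specificity, "f1": self.f1, "auc": self.auc}
        if self.auc_per_class is not None:
            d["auc_per_class"] = dict(self.auc_per_class)
        return d


@dataclass
class CVResult:
    per_repeat: List[Metrics]
    per_fold_accuracy: List[List[float]]
    aggregate: Dict[str, Tuple[float, float]]  # metric -> (mean, sd)
    config: Dict[str, object]


# ---------------------------------------------------------------------------
# folds


def stratified_folds(labels: Sequence, k: int, seed: int) -> np.ndarray:
    """Assign each sample to one of ``k`` folds, stratified by label.

    Per-class fold sizes differ by at most one; deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise RetoctError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    feasible = int(counts.min())
    if feasible < k:
        raise RetoctError(
            f"class {classes[np.argmin(counts)]!r} has only {feasible} samples; "
            f"maximum feasible k is {feasible}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment


# ---------------------------------------------------------------------------
# models


class _RegressionTreeClassifier(BaseEstimator):
    """Decision tree fitted as a regressor on class indices."""

    def __init__(self, random_state: Optional[int] = None, **kwargs):
        self.random_state = random_state
        self.kwargs = kwargs

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        lut = {c: i for i, c in enumerate(self.classes_)}
        target = np.array([lut[v] for v in y], dtype=float)
        self.tree_ = DecisionTreeRegressor(random_state=self.random_state,
                                           **self.kwargs).fit(X, target)
        return self

    def predict(self, X):
        raw = np.clip(np.rint(self.tree_.predict(X)), 0, len(self.classes_) - 1)
        return self.classes_[raw.astype(int)]

    def predict_proba(self, X):
        raw = self.tree_.predict(X)
        dist = np.abs(raw[:, None] - np.arange(len(self.classes_))[None, :])
        prox = np.maximum(1.0 - dist, 1e-6)
        return prox / prox.sum(axis=1, keepdims=True)


def _build_estimator(algorithm: str, params: Dict[str, float], seed: int):
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 100)), random_state=seed)
    if algorithm == "logistic":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", LogisticRegression(max_iter=5000))])
    if algorithm == "svm_linear":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(kernel="linear", probability=True,
                                     random_state=seed))])
    if algorithm == "svm_rbf":
        ks = float(params.get("kernel_scale", 1.0))
        return Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(kernel="rbf", gamma=1.0 / ks**2,
                                     probability=True, random_state=seed))])
    if algorithm == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "tree_classification":
        return DecisionTreeClassifier(random_state=seed)
    if algorithm == "tree_regression":
        return _RegressionTreeClassifier(random_state=seed)
    raise RetoctError(f"unknown algorithm {algorithm!r}; choose one of {ALGORITHMS}")


@dataclass
class Model:
    estimator: object
    classes: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X))

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class score matrix aligned with ``self.classes``."""
        proba = self.estimator.predict_proba(X)
        est_classes = getattr(self.estimator, "classes_", None)
        if est_classes is None:  # pipeline
            est_classes = self.estimator[-1].classes_
        order = [list(est_classes).index(c) for c in self.classes]
        return np.asarray(proba)[:, order]


def train_classifier(X: np.ndarray, y: np.ndarray, algorithm: str,
                     params: Optional[Dict[str, float]] = None,
                     seed: int = 0) -> Model:
    """Fit one classifier from the registry."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise RetoctError("training set must contain at least 2 classes")
    est = _build_estimator(algorithm, params or {}, seed)
    est.fit(np.asarray(X, dtype=float), y)
    return Model(est, classes)


def tune_hyperparams(X: np.ndarray, y: np.ndarray, algorithm: str,
                     grid: Optional[List[Dict[str, float]]] = None,
                     seed: int = 0) -> Dict[str, float]:
    """Pick the grid point maximising accuracy on an inner validation split.

    The split is a stratified ~80/20 partition of the given training data;
    ties keep the earliest grid entry (grids are ordered simplest-first).
    """
    if grid is None:
        grid = DEFAULT_GRIDS.get(algorithm, [{}])
    if not grid:
        raise RetoctError("empty hyperparameter grid")
    if len(grid) == 1:
        return dict(grid[0])
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    k_inner = min(5, int(counts.min()))
    if k_inner < 2:
        return dict(grid[0])
    folds = stratified_folds(y, k_inner, seed)
    val = folds == 0
    Xtr, ytr, Xva, yva = X[~val], y[~val], X[val], y[val]
    best_params, best_acc = None, -1.0
    for params in grid:
        model = train_classifier(Xtr, ytr, algorithm, params, seed)
        acc = float((model.predict(Xva) == yva).mean())
        if acc > best_acc:
            best_acc, best_params = acc, dict(params)
    return best_params


# ---------------------------------------------------------------------------
# metrics


def classification_metrics(truth: Sequence, predictions: Sequence,
                           scores: Optional[np.ndarray] = None,
                           positive_class: Optional[str] = None,
                           classes: Optional[Sequence] = None) -> Metrics:
    """Sensitivity / specificity / f1 / accuracy (percent) and AUC.

    Binary when ``positive_class`` is given; otherwise multi-class, reporting
    overall accuracy and one-vs-rest AUC per class plus the macro average.
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if len(truth) != len(predictions):
        raise RetoctError("truth/prediction length mismatch")
    accuracy = 100.0 * float((truth == predictions).mean())
    if classes is None:
        classes = np.unique(truth)
    classes = list(classes)

    if positive_class is not None:
        pos = truth == positive_class
        pred_pos = predictions == positive_class
        tp = int(np.sum(pos & pred_pos))
        fn = int(np.sum(pos & ~pred_pos))
        tn = int(np.sum(~pos & ~pred_pos))
        fp = int(np.sum(~pos & pred_pos))
        sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 100.0 * (2 * prec * rec / (prec + rec)) if prec + rec else 0.0
        auc = None
        if scores is not None and 0 < pos.sum() < len(pos):
            col = classes.index(positive_class) if np.ndim(scores) == 2 else None
            s = scores[:, col] if col is not None else scores
            auc = float(roc_auc_score(pos, s))
        return Metrics(accuracy=accuracy, sensitivity=sens, specificity=spec,
                       f1=f1, auc=auc)

    auc_per_class = None
    macro = None
    if scores is not None:
        auc_per_class = {}
        for j, c in enumerate(classes):
            ovr = truth == c
            if 0 < ovr.sum() < len(ovr):
                auc_per_class[str(c)] = float(roc_auc_score(ovr, scores[:, j]))
        if auc_per_class:
            macro = float(np.mean(list(auc_per_class.values())))
    return Metrics(accuracy=accuracy, auc=macro, auc_per_class=auc_per_class)


# ---------------------------------------------------------------------------
# repeated cross-validation


def _binarize(labels: np.ndarray) -> np.ndarray:
    return np.where(labels == "normal", "normal", "diseased")


def repeated_kfold_cv(cohort: LabeledCohort, k: int = 15, repeats: int = 10,
                      algorithm: str = "rf",
                      grids: Optional[Dict[str, List[Dict[str, float]]]] = None,
                      seed: int = 0, n_classes: int = 3,
                      positive_class: Optional[str] = None) -> CVResult:
    """Repeated stratified k-fold cross-validation with per-fold tuning.

    ``n_classes=2`` collapses non-normal labels to "diseased" (the positive
    class unless overridden); ``n_classes=3`` runs multi-class and omits
    sensitivity/specificity/f1.  Metrics are pooled over the k folds of each
    repeat; the aggregate is mean and SD over repeats.
    """
    labels = cohort.labels
    if n_classes == 2:
        targets = _binarize(labels) if len(np.unique(labels)) > 2 else labels.copy()
        if positive_class is None:
            positive_class = "diseased" if "diseased" in targets else \
                sorted(c for c in np.unique(targets) if c != "normal")[0]
    elif n_classes == 3:
        targets = labels.copy()
        positive_class = None
    else:
        raise RetoctError("n_classes must be 2 or 3")
    target_cohort = LabeledCohort(cohort.features, targets,
                                  ids=cohort.ids, access_log=cohort.access_log)
    classes = sorted(np.unique(targets))
    grid = (grids or {}).get(algorithm) if grids else None

    per_repeat: List[Metrics] = []
    per_fold_acc: List[List[float]] = []
    for r in range(repeats):
        folds = stratified_folds(labels, k, seed + 1009 * r)
        pooled_truth: List[np.ndarray] = []
        pooled_pred: List[np.ndarray] = []
        pooled_scores: List[np.ndarray] = []
        fold_acc: List[float] = []
        for f in range(k):
            test_idx = np.nonzero(folds == f)[0]
            train_idx = np.nonzero(folds != f)[0]
            Xtr, ytr = target_cohort.subset(train_idx, f"r{r}/f{f}/train")
            fold_seed = seed + 7919 * r + 13 * f
            params = tune_hyperparams(Xtr, ytr, algorithm, grid, fold_seed)
            model = train_classifier(Xtr, ytr, algorithm, params, fold_seed)
            Xte, yte = target_cohort.subset(test_idx, f"r{r}/f{f}/test")
            pred = model.predict(Xte)
            score = model.scores(Xte)
            # align score columns with the global class list
            full = np.zeros((len(pred), len(classes)))
            for j, c in enumerate(model.classes):
                full[:, classes.index(c)] = score[:, j]
            pooled_truth.append(yte)
            pooled_pred.append(pred)
            pooled_scores.append(full)
            fold_acc.append(100.0 * float((pred == yte).mean()))
        truth = np.concatenate(pooled_truth)
        pred = np.concatenate(pooled_pred)
        sc = np.vstack(pooled_scores)
        per_repeat.append(classification_metrics(truth, pred, sc,
                                                 positive_class, classes))
        per_fold_acc.append(fold_acc)

    aggregate: Dict[str, Tuple[float, float]] = {}
    for key in ("accuracy", "sensitivity", "specificity", "f1", "auc"):
        vals = [getattr(m, key) for m in per_repeat]
        if all(v is not None and np.isfinite(v) for v in vals):
            arr = np.array(vals, dtype=float)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            aggregate[key] = (float(arr.mean()), sd)
    return CVResult(
        per_repeat=per_repeat,
        per_fold_accuracy=per_fold_acc,
        aggregate=aggregate,
        config={"k": k, "repeats": repeats, "algorithm": algorithm,
                "seed": seed, "n_classes": n_classes,
                "positive_class": positive_class,
                "grid": grid if grid is not None else DEFAULT_GRIDS.get(algorithm, [{}])},
    )
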