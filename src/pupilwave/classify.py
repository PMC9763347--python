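"""Train/test harness: LR, SVM, KNN on the slope-feature matrix.

A single stratified random split (default 67% train) mirrors the
evaluation design the feature pipeline targets.  Logistic regression
is thresholded at the Youden-index optimum — computed on the *train*
predictions to avoid leaking the test partition — while SVM and KNN
use their native decision rules.  Metrics treat *case* as the positive
class: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy in
percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dwt import DomainError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

MODELS = ("lr", "svm", "knn")


@dataclass
class EvaluationResult:
    model: str
    sensitivity: float
    specificity: float
    accuracy: float  # percent
    confusion: dict = field(default_factory=dict)  # tp, fn, tn, fp
    threshold: float | None = None  # LR only
    roc: list | None = None  # LR only: (fpr, tpr) pairs on test
    split_seed: int | None = None
    params: dict = field(default_factory=dict)


def split(
    fm: FeatureMatrix, train_fraction: float = 0.67, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split: round(train_fraction * n) subjects per
    class go to train (round half up), the rest to test.  Returns
    (train_idx, test_idx); disjoint and exhaustive, reproducible by
    seed."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in np.unique(fm.y):
        members = np.flatnonzero(fm.y == label)
        if members.size < 3:
            raise DomainError(
                f"class {label} has only {members.size} subjects; need >= 3"
            )
        n_train = int(np.floor(train_fraction * members.size + 0.5))
        n_train = min(max(n_train, 1), members.size - 1)
        perm = rng.permutation(members)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise DomainError("both classes must be present")


def youden_threshold(
    probabilities: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Threshold maximizing the Youden index
    gamma = (sensitivity + specificity - 1) / sqrt(2).

    Every distinct probability is a candidate; prediction is *case*
    when probability >= threshold; ties in gamma break toward the
    smaller threshold.  Returns (threshold, gamma)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    best_t, best_g = None, -np.inf
    for t in np.unique(p):
        pred = p >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        g = (sens + spec - 1) / np.sqrt(2)
        if g > best_g:  # strict: ties keep the smaller threshold
            best_t, best_g = float(t), float(g)
    return best_t, best_g


def roc_curve(probabilities: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    """ROC staircase (1-specificity, sensitivity) over all thresholds,
    from (0, 0) down through every distinct probability to (1, 1)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_two_classes(y)
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    points = [(0.0, 0.0)]
    for t in np.sort(np.unique(p))[::-1]:
        pred = p >= t
        fpr = (pred & (y == 0)).sum() / n_neg
        tpr = (pred & (y == 1)).sum() / n_pos
        points.append((float(fpr), float(tpr)))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def _metrics(pred: np.ndarray, y: np.ndarray) -> tuple[float, float, float, dict]:
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / y.size
    return sens, spec, acc, {"tp": tp, "fn": fn, "tn": tn, "fp": fp}


def _impute(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray):
    """Median-impute masked features: within class on train, with
    overall train medians on test (labels are unknown at test time)."""
    X_train = X_train.copy()
    X_test = X_test.copy()
    overall = np.nanmedian(X_train, axis=0)
    overall = np.nan_to_num(overall, nan=0.0)
    for label in np.unique(y_train):
        rows = y_train == label
        med = np.nanmedian(X_train[rows], axis=0)
        med = np.where(np.isnan(med), overall, med)
        block = X_train[rows]
        X_train[rows] = np.where(np.isnan(block), med[None, :], block)
    X_test = np.where(np.isnan(X_test), overall[None, :], X_test)
    return X_train, X_test


def evaluate_models(
    fm: FeatureMatrix,
    selected: np.ndarray | None = None,
    models: tuple[str, ...] = MODELS,
    seed: int | None = None,
    train_fraction: float = 0.67,
    standardize: bool = True,
    svm_params: dict | None = None,
    knn_k: int = 5,
) -> list[EvaluationResult]:
    """Fit each requested model on the train partition (restricted to
    ``selected`` feature columns) and report test metrics.

    SVM uses an RBF kernel with scikit-learn defaults and KNN k = 5
    unless overridden; features are z-scored with train-fit parameters
    before SVM/KNN (and LR) unless ``standardize=False``.
    """
    for m in models:
        if m not in MODELS:
            raise DomainError(f"unknown model {m!r}; choose among {MODELS}")
    cols = np.arange(fm.n_features) if selected is None else np.asarray(selected, int)
    if cols.size == 0:
        raise DomainError("no features selected")
    train_idx, test_idx = split(fm, train_fraction, seed)
    X_tr, X_te = fm.X[np.ix_(train_idx, cols)], fm.X[np.ix_(test_idx, cols)]
    y_tr, y_te = fm.y[train_idx], fm.y[test_idx]
    _check_two_classes(y_tr)
    X_tr, X_te = _impute(X_tr, y_tr, X_te)
    if standardize:
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)

    results = []
    for name in models:
        threshold = roc = None
        params: dict = {}
        if name == "lr":
            clf = LogisticRegression(max_iter=1000)
            clf.fit(X_tr, y_tr)
            threshold, gamma = youden_threshold(clf.predict_proba(X_tr)[:, 1], y_tr)
            p_te = clf.predict_proba(X_te)[:, 1]
            pred = p_te >= threshold
            roc = roc_curve(p_te, y_te) if np.unique(y_te).size == 2 else None
            params = {"max_iter": 1000, "train_gamma": gamma}
        elif name == "svm":
            params = {"kernel": "rbf", "C": 1.0, "gamma": "scale"}
            if svm_params:
                params.update(svm_params)
            clf = SVC(**params)
            clf.fit(X_tr, y_tr)
            pred = clf.predict(X_te).astype(bool)
        else:
            params = {"n_neighbors": knn_k}
            clf = KNeighborsClassifier(n_neighbors=knn_k)
            clf.fit(X_tr, y_tr)
            pred = clf.predict(X_te).astype(bool)
        sens, spec, acc, confusion = _metrics(np.asarray(pred, bool), y_te)
        results.append(
            EvaluationResult(
                model=name, sensitivity=sens, specificity=spec, accuracy=acc,
                confusion=confusion, threshold=threshold, roc=roc,
                split_seed=seed, params=params,
            )
        )
        logger.info("%s: acc %.2f%% sens %.2f spec %.2f", name, acc, sens, spec)
    return results
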