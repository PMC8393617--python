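"""Classifier training, cross-validation and the full evaluation metric suite.

The classifier family mirrors the common toolbox presets for this task:
ensembles of bagged trees (the best performer for CAP phase detection),
boosted trees, an RBF support vector machine, k-nearest neighbours,
logistic regression and a single unconstrained ("fine") decision tree.
Evaluation uses sample-wise stratified 10-fold cross-validation with
per-fold predictions pooled into one confusion matrix, from which the
reported metrics are computed: average classification accuracy (ACA, the
mean of per-class accuracies), precision, recall and F1 for phase A,
Cohen's kappa and the ROC AUC (rank / Mann-Whitney formulation with
midranks).  For balanced binary data ACA and kappa are tied exactly by
``kappa = 2 ACA/100 - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "CLASSIFIER_KINDS",
    "TrainedModel",
    "ClassificationMetrics",
    "train",
    "crossvalidate",
    "metrics_from_confusion",
    "auc_from_scores",
]

CLASS_ORDER = ("A", "B")

CLASSIFIER_KINDS = (
    "bagged_trees",
    "boosted_trees",
    "svm_rbf",
    "knn",
    "logistic",
    "fine_tree",
)


def _make_estimator(kind: str, params: dict | None, seed: int | None):
    params = dict(params or {})
    if kind == "bagged_trees":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=params.pop("n_estimators", 30),
            random_state=seed,
            **params,
        )
    if kind == "boosted_trees":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(
                max_depth=params.pop("max_depth", 20), random_state=seed
            ),
            n_estimators=params.pop("n_estimators", 30),
            learning_rate=params.pop("learning_rate", 0.1),
            random_state=seed,
            **params,
        )
    if kind == "svm_rbf":
        return SVC(kernel="rbf", random_state=seed, **params)
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=params.pop("n_neighbors", 10), **params)
    if kind == "logistic":
        return LogisticRegression(max_iter=params.pop("max_iter", 2000), **params)
    if kind == "fine_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


@dataclass
class TrainedModel:
    """A fitted classifier with a probability-like score for phase A."""

    kind: str
    estimator: object
    classes: tuple[str, str] = CLASS_ORDER

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)

    def score_a(self, X: np.ndarray) -> np.ndarray:
        """Score in [0, 1], higher = more phase-A-like."""
        est = self.estimator
        pos = self.classes[0]
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            col = list(est.classes_).index(pos)
            return proba[:, col]
        dec = est.decision_function(X)
        # decision_function is oriented towards classes_[1]
        if list(est.classes_)[1] != pos:
            dec = -dec
        return expit(dec)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"single-class input (labels all {classes.tolist()})")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    return X, y


def train(
    kind: str,
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    params: dict | None = None,
    seed: int | None = 0,
) -> TrainedModel:
    """Fit one classifier; deterministic for a given seed."""
    if isinstance(X, FeatureMatrix):
        X, y = X.values, X.labels
    X, y = _check_xy(X, y)
    est = _make_estimator(kind, params, seed)
    est.fit(X, y)
    return TrainedModel(kind=kind, estimator=est)


@dataclass
class ClassificationMetrics:
    """Confusion matrix (predicted x actual) and the derived metric suite.

    ``col_pct`` normalizes each actual-class column to 100.  ``aca`` is in
    percent; ``pcn/rcl/f1`` refer to phase A as the positive class.
    """

    confusion: np.ndarray
    col_pct: np.ndarray
    aca: float
    pcn: float
    rcl: float
    f1: float
    kappa: float
    auc: float | None = None
    fold_accuracies: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "confusion_counts": self.confusion.tolist(),
            "confusion_col_pct": np.round(self.col_pct, 2).tolist(),
            "aca": round(self.aca, 2),
            "pcn": round(self.pcn, 2),
            "rcl": round(self.rcl, 2),
            "f1": round(self.f1, 2),
            "kappa": round(self.kappa, 2),
            "auc": None if self.auc is None else round(self.auc, 2),
            "fold_accuracies": [round(a, 4) for a in self.fold_accuracies],
        }


def metrics_from_confusion(
    col_pct: np.ndarray,
    priors: tuple[float, float] = (0.5, 0.5),
    auc: float | None = None,
    counts: np.ndarray | None = None,
    fold_accuracies: list[float] | None = None,
) -> ClassificationMetrics:
    """Metric suite from a column-normalized 2x2 confusion matrix.

    Layout: rows = predicted (A, B), columns = actual (A, B); each column
    sums to 100.  ``priors`` are the actual-class proportions (0.5, 0.5 for
    balanced data), used to weight columns into joint probabilities for
    precision and kappa.
    """
    col_pct = np.asarray(col_pct, dtype=float)
    if col_pct.shape != (2, 2):
        raise ValueError("expected a 2x2 matrix")
    sums = col_pct.sum(axis=0)
    if np.max(np.abs(sums - 100.0)) > 0.5:
        raise ValueError(f"columns must sum to 100 +- 0.5, got {sums.tolist()}")
    priors_arr = np.asarray(priors, dtype=float)
    if abs(priors_arr.sum() - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    joint = (col_pct / sums) * priors_arr  # joint[pred, actual]
    rcl = col_pct[0, 0] / sums[0]
    pcn = joint[0, 0] / joint[0].sum() if joint[0].sum() > 0 else 0.0
    aca = 100.0 * float(np.mean(np.diag(col_pct / sums)))
    p_o = float(np.trace(joint))
    p_e = float(joint.sum(axis=1) @ joint.sum(axis=0))
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    f1 = 2 * pcn * rcl / (pcn + rcl) if pcn + rcl > 0 else 0.0
    return ClassificationMetrics(
        confusion=counts if counts is not None else np.round(col_pct).astype(int),
        col_pct=100.0 * col_pct / sums,
        aca=aca,
        pcn=float(pcn),
        rcl=float(rcl),
        f1=float(f1),
        kappa=float(kappa),
        auc=auc,
        fold_accuracies=fold_accuracies or [],
    )


def auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC area via the Mann-Whitney rank statistic (midranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == CLASS_ORDER[0]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def crossvalidate(
    kind: str,
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    k: int = 10,
    seed: int | None = 0,
    params: dict | None = None,
    model_seed: int | None = None,
) -> ClassificationMetrics:
    """Stratified sample-wise k-fold CV with pooled confusion and scores.

    ``seed`` fixes the fold assignment; ``model_seed`` (defaulting to
    ``seed``) fixes the per-fold model fits, so the two stochastic stages
    are independently reproducible.
    """
    if model_seed is None:
        model_seed = seed
    if isinstance(X, FeatureMatrix):
        X, y = X.values, X.labels
    X, y = _check_xy(X, y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError(f"n = {len(y)} smaller than k = {k}")
    if k == len(y):  # leave-one-out cannot be stratified
        skf = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    counts = np.zeros((2, 2), dtype=int)
    all_scores = np.empty(len(y))
    all_pred = np.empty(len(y), dtype=y.dtype)
    folds: list[float] = []
    for tr, te in skf.split(X, y):
        model = train(kind, X[tr], y[tr], params=params, seed=model_seed)
        pred = model.predict(X[te])
        all_pred[te] = pred
        all_scores[te] = model.score_a(X[te])
        folds.append(float(np.mean(pred == y[te])))
    for i, pred_label in enumerate(CLASS_ORDER):
        for j, true_label in enumerate(CLASS_ORDER):
            counts[i, j] = int(np.sum((all_pred == pred_label) & (y == true_label)))
    col_tot = counts.sum(axis=0)
    col_pct = 100.0 * counts / np.where(col_tot > 0, col_tot, 1)
    priors = (col_tot[0] / col_tot.sum(), col_tot[1] / col_tot.sum())
    auc = auc_from_scores(all_scores, y)
    return metrics_from_confusion(
        col_pct, priors=priors, auc=auc, counts=counts, fold_accuracies=folds
    )
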