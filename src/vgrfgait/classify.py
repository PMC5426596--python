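"""Leave-one-subject-out classifier comparison for gait feature matrices.

Four classifier families are compared on the per-subject feature
vectors: support vector machines with linear, Gaussian (RBF), quadratic
and cubic kernels, k-nearest neighbours (k = 10, Euclidean, equal
weights), a Gini decision tree capped at 20 splits, and an AdaBoost
ensemble of 30 such trees with learning rate 0.1 (a bagged random
forest is also available).  Evaluation is leave-one-subject-out: each
subject in turn is held out, standardization (and PCA, when configured)
is fit on the remaining subjects only, the model is trained and the
held-out subject predicted; pooled out-of-fold predictions give the
confusion matrix, accuracy, sensitivity, specificity, and the AUC of
the pooled continuous decision scores.

Kernels (on standardized feature vectors u, v):

    linear     K(u, v) = u·v
    rbf        K(u, v) = exp(−γ‖u − v‖²)
    quadratic  K(u, v) = (u·v + 1)²
    cubic      K(u, v) = (u·v + 1)³

The PD group is the positive class, so sensitivity is the PD-detection
rate and specificity the control-rejection rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

POSITIVE_LABEL = 1  # pd


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration of the comparison table.

    ``family``: svm | knn | tree | boosted_ensemble | random_forest.
    ``kernel`` applies to SVM only.  ``max_splits`` caps the number of
    internal splits of a tree (20 as in the reference configuration).
    Distance- and kernel-based families are z-score standardized inside
    each training fold; trees and ensembles are scale-invariant and run
    on raw features.  ``pca_variance`` (0, 1] retains the smallest
    number of principal components reaching that cumulative explained
    variance, fit on the training fold only.
    """

    name: str
    family: str
    kernel: str | None = None        # linear | rbf | quadratic | cubic
    C: float = 1.0
    gamma: str | float = "scale"     # "scale" = 1 / (n_features · Var(X))
    k: int = 10
    max_splits: int = 20
    n_learners: int = 30
    learning_rate: float = 0.1
    standardize: bool | None = None  # None = family default
    pca_variance: float | None = None

    def __post_init__(self) -> None:
        if (self.family == "svm") != (self.kernel is not None):
            raise ValueError("kernel must be set iff family is 'svm'")
        if self.family == "svm" and self.kernel not in ("linear", "rbf", "quadratic", "cubic"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.pca_variance is not None and not 0 < self.pca_variance <= 1:
            raise ValueError("pca_variance must lie in (0, 1]")

    @property
    def standardized(self) -> bool:
        if self.standardize is not None:
            return self.standardize
        return self.family in ("svm", "knn")


def kernel_value(u: np.ndarray, v: np.ndarray, spec: ClassifierSpec,
                 gamma: float = 1.0) -> float:
    """Evaluate the spec's SVM kernel on a pair of feature vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal dimension")
    if spec.kernel == "linear":
        return float(u @ v)
    if spec.kernel == "rbf":
        return float(np.exp(-gamma * np.sum((u - v) ** 2)))
    if spec.kernel == "quadratic":
        return float((u @ v + 1.0) ** 2)
    if spec.kernel == "cubic":
        return float((u @ v + 1.0) ** 3)
    raise ValueError(f"spec has no kernel ({spec.family})")


def _make_estimator(spec: ClassifierSpec, seed: int):
    if spec.family == "svm":
        if spec.kernel == "linear":
            return SVC(kernel="linear", C=spec.C)
        if spec.kernel == "rbf":
            return SVC(kernel="rbf", C=spec.C, gamma=spec.gamma)
        degree = 2 if spec.kernel == "quadratic" else 3
        return SVC(kernel="poly", degree=degree, gamma=1.0, coef0=1.0, C=spec.C)
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k, weights="uniform",
                                    metric="euclidean")
    if spec.family == "tree":
        # max_leaf_nodes = splits + 1 under best-first growth
        return DecisionTreeClassifier(criterion="gini",
                                      max_leaf_nodes=spec.max_splits + 1,
                                      random_state=seed)
    if spec.family == "boosted_ensemble":
        base = DecisionTreeClassifier(criterion="gini",
                                      max_leaf_nodes=spec.max_splits + 1,
                                      random_state=seed)
        return AdaBoostClassifier(estimator=base, n_estimators=spec.n_learners,
                                  learning_rate=spec.learning_rate, random_state=seed)
    if spec.family == "random_forest":
        return RandomForestClassifier(n_estimators=spec.n_learners,
                                      max_leaf_nodes=spec.max_splits + 1,
                                      random_state=seed)
    raise ValueError(f"unknown classifier family {spec.family!r}")


@dataclass
class EvaluationResult:
    """Pooled leave-one-subject-out outcome for one classifier spec."""

    spec_name: str
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # continuous decision scores, higher = more PD-like
    fold_errors: list[str] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return int(np.sum((self.y_true == POSITIVE_LABEL) & (self.y_pred == POSITIVE_LABEL)))

    @property
    def tn(self) -> int:
        return int(np.sum((self.y_true != POSITIVE_LABEL) & (self.y_pred != POSITIVE_LABEL)))

    @property
    def fp(self) -> int:
        return int(np.sum((self.y_true != POSITIVE_LABEL) & (self.y_pred == POSITIVE_LABEL)))

    @property
    def fn(self) -> int:
        return int(np.sum((self.y_true == POSITIVE_LABEL) & (self.y_pred != POSITIVE_LABEL)))

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / len(self.y_true)

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def auc(self) -> float:
        if len(np.unique(self.y_true)) < 2:
            return float("nan")
        return float(roc_auc_score(self.y_true, self.scores))

    def metrics(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc}


def pca_reduce(train_X: np.ndarray, test_X: np.ndarray,
               variance_fraction: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Project train/test onto the fewest train-fit components reaching
    the requested cumulative explained variance.

    The transform is fit on ``train_X`` only; ``test_X`` is projected
    with it.  ``variance_fraction=1.0`` keeps every component with
    nonzero variance.
    """
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must lie in (0, 1]")
    if len(train_X) < 2:
        raise ValueError("PCA needs at least 2 training samples")
    pca = PCA()
    train_Z = pca.fit_transform(train_X)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    if variance_fraction == 1.0:
        n_components = int(np.sum(pca.explained_variance_ > 1e-12))
        n_components = max(n_components, 1)
    else:
        n_components = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
        n_components = min(n_components, len(ratios))
    test_Z = pca.transform(np.atleast_2d(test_X))
    return train_Z[:, :n_components], test_Z[:, :n_components], n_components


def _fit_fold(train_X: np.ndarray, spec: ClassifierSpec):
    """Fold-local transform fit on training subjects only (no leakage)."""
    scaler = StandardScaler().fit(train_X) if spec.standardized else None

    def transform(X: np.ndarray) -> np.ndarray:
        return scaler.transform(X) if scaler is not None else X

    return transform


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    proba = model.predict_proba(X)
    pos_col = int(np.argmax(model.classes_ == POSITIVE_LABEL))
    return np.asarray(proba[:, pos_col], dtype=float)


def loo_evaluate(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec,
                 seed: int = 0) -> EvaluationResult:
    """Leave-one-subject-out evaluation of one classifier spec.

    One fold per subject; standardization and PCA are fit inside each
    training fold.  Deterministic given (X, y, spec, seed).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    y_pred = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    fold_errors: list[str] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_X, train_y = X[mask], y[mask]
        if len(np.unique(train_y)) < 2:
            fold_errors.append(f"fold {i}: a class is missing from the training set")
            y_pred[i] = 1 - y[i]
            scores[i] = 0.0
            continue
        transform = _fit_fold(train_X, spec)
        Ztr = transform(train_X)
        Zte = transform(X[i:i + 1])
        if spec.pca_variance is not None:
            Ztr, Zte, _ = pca_reduce(Ztr, Zte, spec.pca_variance)
        model = _make_estimator(spec, seed)
        model.fit(Ztr, train_y)
        y_pred[i] = int(model.predict(Zte)[0])
        scores[i] = float(_decision_scores(model, Zte)[0])
    return EvaluationResult(spec_name=spec.name, y_true=y.copy(), y_pred=y_pred,
                            scores=scores, fold_errors=fold_errors)


def default_specs() -> list[ClassifierSpec]:
    """The comparison table: four SVM kernels, kNN, tree, AdaBoost, cubic+PCA."""
    return [
        ClassifierSpec(name="svm_linear", family="svm", kernel="linear"),
        ClassifierSpec(name="svm_rbf", family="svm", kernel="rbf"),
        ClassifierSpec(name="svm_quadratic", family="svm", kernel="quadratic"),
        ClassifierSpec(name="svm_cubic", family="svm", kernel="cubic"),
        ClassifierSpec(name="knn_k10", family="knn", k=10),
        ClassifierSpec(name="decision_tree", family="tree"),
        ClassifierSpec(name="adaboost", family="boosted_ensemble"),
        ClassifierSpec(name="svm_cubic_pca95", family="svm", kernel="cubic",
                       pca_variance=0.95),
    ]


def compare_classifiers(X: np.ndarray, y: np.ndarray,
                        specs: list[ClassifierSpec] | None = None,
                        seed: int = 0) -> dict[str, EvaluationResult]:
    """Evaluate every spec under LOO; a failing spec is reported, not fatal."""
    specs = specs if specs is not None else default_specs()
    results: dict[str, EvaluationResult] = {}
    for spec in specs:
        try:
            results[spec.name] = loo_evaluate(X, y, spec, seed=seed)
        except Exception as exc:  # noqa: BLE001 - report per-spec failures
            results[spec.name] = EvaluationResult(
                spec_name=spec.name, y_true=np.asarray(y, dtype=int),
                y_pred=np.full(len(y), -1), scores=np.zeros(len(y)),
                fold_errors=[f"spec failed: {exc}"])
    return results


def metrics_frame(results: dict[str, EvaluationResult]) -> pd.DataFrame:
    """Tidy metrics table, one row per classifier spec."""
    rows = []
    for name, res in results.items():
        row = {"classifier": name}
        row.update(res.metrics())
        row.update(tp=res.tp, fp=res.fp, tn=res.tn, fn=res.fn,
                   n_fold_errors=len(res.fold_errors))
        rows.append(row)
    return pd.DataFrame(rows)
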