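"""Feature selection: sequential forward wrapper, mRMR, and MI ranking.

Three selectors over the 13-feature gait matrix:

* a single-pass sequential forward wrapper seeded with the timing
  variability features and scored by leave-one-subject-out linear-SVM
  accuracy,
* Peng et al.'s minimum-redundancy maximum-relevance (mRMR) greedy
  selection on discretized features, and
* plain mutual-information ranking against the class label.

Mutual information is the plug-in estimate on empirical discrete
distributions, in bits.  Continuous features are discretized into three
bins split at mean ± 0.5·SD (mRMR's customary scheme) or into
equal-frequency quantile bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd


@dataclass
class SelectionResult:
    """Outcome of one feature-selection run.

    ``selected`` is ordered (selection order for SFS/mRMR, decreasing
    weight for ranking).  ``trace`` holds per-step diagnostics: wrapper
    accuracies for SFS, relevance/redundancy scores for mRMR, MI weights
    for the ranking.
    """

    method: str
    selected: list[str]
    trace: list[dict] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"method": self.method, "selected": list(self.selected),
                "scores": {k: float(v) for k, v in self.scores.items()},
                "trace": self.trace}


# ---------------------------------------------------------------------------
# Mutual information on discrete data
# ---------------------------------------------------------------------------

def mutual_information(a: Sequence, b: Sequence) -> float:
    """Plug-in mutual information I(a;b) in bits on the empirical joint.

    Nonnegative; I(a;a) equals the empirical entropy H(a).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    if a.size == 0:
        raise ValueError("sequences must be non-empty")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))
    return max(mi, 0.0)  # clip tiny negative rounding residue


def discretize(column: np.ndarray, scheme: str = "mean_sd", n_bins: int = 3) -> np.ndarray:
    """Integer-bin a continuous feature column.

    ``mean_sd``: three bins split at mean ± 0.5·SD.  ``quantile``:
    ``n_bins`` equal-frequency bins.
    """
    column = np.asarray(column, dtype=float)
    if scheme == "mean_sd":
        mu, sd = column.mean(), column.std()
        edges = np.array([mu - 0.5 * sd, mu + 0.5 * sd])
    elif scheme == "quantile":
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        edges = np.quantile(column, qs)
    else:
        raise ValueError(f"unknown discretization scheme {scheme!r}")
    return np.digitize(column, edges)


def _as_matrix(X, feature_names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    return X, list(feature_names)


# ---------------------------------------------------------------------------
# MI ranking and mRMR
# ---------------------------------------------------------------------------

def mi_rank(X, y, feature_names=None, scheme: str = "mean_sd") -> SelectionResult:
    """Rank features by decreasing mutual information with the label.

    Weights are the MI values in bits; ties keep the input column order.
    """
    X, names = _as_matrix(X, feature_names)
    y = np.asarray(y)
    weights = {name: mutual_information(discretize(X[:, j], scheme), y)
               for j, name in enumerate(names)}
    order = sorted(names, key=lambda n: (-weights[n], names.index(n)))
    return SelectionResult(method="mi_rank", selected=order, scores=weights,
                           trace=[{"feature": n, "mi_bits": weights[n]} for n in order])


def mrmr_select(X, y, k: int, feature_names=None, criterion: str = "MID",
                scheme: str = "mean_sd") -> SelectionResult:
    """Greedy minimum-redundancy maximum-relevance selection of ``k`` features.

    The first feature maximizes relevance I(f; y); each subsequent pick
    maximizes relevance − redundancy (``MID``) or relevance / redundancy
    (``MIQ``), where redundancy is the mean MI with the already-selected
    features.  Ties break toward the earlier input column, so the result
    is deterministic and invariant to column permutation up to ties.
    """
    if criterion not in ("MID", "MIQ"):
        raise ValueError(f"criterion must be MID or MIQ, got {criterion!r}")
    X, names = _as_matrix(X, feature_names)
    y = np.asarray(y)
    if not 0 < k <= len(names):
        raise ValueError(f"k must be in 1..{len(names)}, got {k}")

    D = np.column_stack([discretize(X[:, j], scheme) for j in range(X.shape[1])])
    relevance = np.array([mutual_information(D[:, j], y) for j in range(D.shape[1])])
    pairwise = {}

    def mi_ff(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in pairwise:
            pairwise[key] = mutual_information(D[:, key[0]], D[:, key[1]])
        return pairwise[key]

    selected: list[int] = []
    trace: list[dict] = []
    while len(selected) < k:
        best_j, best_score, best_rel, best_red = None, None, None, None
        for j in range(len(names)):
            if j in selected:
                continue
            if not selected:
                red = 0.0
            else:
                red = float(np.mean([mi_ff(j, s) for s in selected]))
            if criterion == "MID":
                score = relevance[j] - red
            else:
                score = relevance[j] / red if red > 0 else np.inf
            if best_score is None or score > best_score:
                best_j, best_score, best_rel, best_red = j, score, relevance[j], red
        selected.append(best_j)
        trace.append({"feature": names[best_j], "score": float(best_score),
                      "relevance_bits": float(best_rel), "redundancy_bits": float(best_red)})
    chosen = [names[j] for j in selected]
    return SelectionResult(method=f"mrmr_{criterion.lower()}", selected=chosen,
                           scores={names[j]: float(relevance[j]) for j in selected},
                           trace=trace)


# ---------------------------------------------------------------------------
# Sequential forward wrapper
# ---------------------------------------------------------------------------

def _default_evaluator() -> Callable[[np.ndarray, np.ndarray], float]:
    from .classify import ClassifierSpec, loo_evaluate

    spec = ClassifierSpec(name="sfs_wrapper", family="svm", kernel="linear")

    def evaluate(X: np.ndarray, y: np.ndarray) -> float:
        return loo_evaluate(X, y, spec, seed=0).accuracy

    return evaluate


def sequential_forward_select(X, y, feature_names=None,
                              seed_features: Sequence[str] = ("cv_stride", "cv_swing"),
                              order: Sequence[str] | None = None,
                              evaluator: Callable | None = None) -> SelectionResult:
    """Single-pass sequential forward selection with a wrapper evaluator.

    The seed features (timing variability, when present) enter the model
    unconditionally; the remaining candidates are visited once in
    ``order`` (default: the feature-table column order) and each is kept
    iff the wrapper accuracy with it is at least the accuracy without it
    — only a strict decrease rejects a candidate.  The default evaluator
    is leave-one-subject-out linear-SVM accuracy.
    """
    X, names = _as_matrix(X, feature_names)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("sequential forward selection needs both classes present")
    evaluator = evaluator or _default_evaluator()
    col = {n: j for j, n in enumerate(names)}

    current: list[str] = [f for f in seed_features if f in col]
    candidates = [f for f in (order or names) if f in col and f not in current]

    trace: list[dict] = []
    if current:
        acc = evaluator(X[:, [col[f] for f in current]], y)
        trace.append({"added": list(current), "accuracy": acc, "kept": True})
    else:
        acc = None
    for f in candidates:
        trial = current + [f]
        trial_acc = evaluator(X[:, [col[g] for g in trial]], y)
        keep = acc is None or trial_acc >= acc
        trace.append({"added": [f], "accuracy": trial_acc, "kept": keep})
        if keep:
            current = trial
            acc = trial_acc
    return SelectionResult(method="sfs", selected=current, trace=trace,
                           scores={"wrapper_accuracy": float(acc)})
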