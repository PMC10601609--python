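"""Linear SVM training in dual form, margin geometry, and the benchmark
classifiers used by the filter-method comparison.

The linear SVM is solved through libsvm's SMO (via scikit-learn), and the
quantities the feature-selection fitness function needs are read off the
dual solution: the multipliers alpha_i, the support vectors, the decision
boundary w = sum_i alpha_i y_i x_i over the active feature subset, and the
geometric margin width 2 / ||w||_2 between the two supporting hyperplanes.

Labels here are {-1, +1}; the dataset layer's {0, 1} coding is mapped with
:func:`to_pm1`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SVMModel",
    "BenchmarkClassifierSpec",
    "DegenerateModelError",
    "to_pm1",
    "train_linear_svm",
    "decision_boundary",
    "margin_width",
    "predict",
    "accuracy",
    "train_benchmark_classifier",
]

_ZERO_W_TOL = 1e-10


class DegenerateModelError(ValueError):
    """The trained model has no usable decision boundary (zero weight vector)."""


def to_pm1(y: np.ndarray) -> np.ndarray:
    """Map {0, 1} labels to {-1, +1}; labels already in {-1, +1} pass through."""
    y = np.asarray(y)
    out = np.where(y <= 0, -1, 1)
    return out.astype(int)


@dataclass
class SVMModel:
    """A trained soft-margin linear SVM in dual form.

    ``alphas`` are the Lagrange multipliers of every training sample
    (zero off the support set), satisfying 0 <= alpha_i <= C and
    sum_i alpha_i y_i = 0.  ``w`` is the decision boundary
    sum_i alpha_i y_i x_i over the active features, and ``margin_width`` is
    the geometric width 2 / ||w||_2 of the separating slab (infinite when
    the model is degenerate).  When the model was trained on standardized
    inputs, ``scale_mean``/``scale_sd`` hold the training-split statistics
    and ``predict`` applies them to new data.
    """

    alphas: np.ndarray
    support_indices: np.ndarray
    w: np.ndarray
    bias: float
    C: float
    degenerate: bool = False
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None
    feature_subset: np.ndarray | None = None

    @property
    def margin_width(self) -> float:
        norm = float(np.linalg.norm(self.w))
        return np.inf if norm < _ZERO_W_TOL else 2.0 / norm

    def to_dict(self) -> dict[str, Any]:
        return {
            "alphas": self.alphas.tolist(),
            "support_indices": self.support_indices.tolist(),
            "w": self.w.tolist(),
            "bias": self.bias,
            "C": self.C,
            "degenerate": self.degenerate,
            "feature_subset": None
            if self.feature_subset is None
            else np.asarray(self.feature_subset, dtype=int).tolist(),
        }


def train_linear_svm(
    X_active: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    standardize: bool = False,
) -> SVMModel:
    """Solve the soft-margin linear SVM dual on a feature-subset matrix.

    Parameters
    ----------
    X_active
        Training matrix restricted to the active feature subset
        (n_samples x m).
    y
        Labels in {-1, +1} (or {0, 1}, which are remapped).
    C
        Soft-margin box constraint; pass a large value (e.g. 1e6) for
        effectively hard-margin behaviour on separable data.
    standardize
        If True, z-score each column with its own mean/sd before the dual
        solve and remember the statistics for prediction.  Margin and w then
        live in standardized coordinates, which makes margins comparable
        across heterogeneous feature subsets; the default (False) preserves
        the raw-scale geometry (margin covariant with input scaling).
    """
    X = np.asarray(X_active, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = to_pm1(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class; SVM needs both")
    if np.isnan(X).any():
        raise ValueError("training matrix contains missing values")
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")

    mean = sd = None
    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        X = (X - mean) / sd

    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)

    alphas = np.zeros(X.shape[0])
    # dual_coef_ holds alpha_i * y_i for the support vectors
    alphas[clf.support_] = np.abs(clf.dual_coef_[0])
    w = clf.coef_[0].astype(float)
    degenerate = float(np.linalg.norm(w)) < _ZERO_W_TOL
    return SVMModel(
        alphas=alphas,
        support_indices=clf.support_.astype(int),
        w=w,
        bias=float(clf.intercept_[0]),
        C=C,
        degenerate=degenerate,
        scale_mean=mean,
        scale_sd=sd,
    )


def decision_boundary(model: SVMModel) -> np.ndarray:
    """Weight vector sum_i alpha_i y_i x_i of the trained model.

    Zero vectors are returned as-is (the model carries a ``degenerate``
    flag); callers that need a margin should use :func:`margin_width`,
    which rejects them.
    """
    if model.w is None:
        raise ValueError("model has no trained decision boundary")
    return np.asarray(model.w, dtype=float)


def margin_width(model: SVMModel) -> float:
    """Geometric width 2 / ||w||_2 of the separating slab."""
    if model.degenerate:
        raise DegenerateModelError("zero weight vector: margin width is undefined")
    return model.margin_width


def predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Predict {-1, +1} labels with the linear decision function."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if model.scale_mean is not None:
        X = (X - model.scale_mean) / model.scale_sd
    scores = X @ model.w + model.bias
    return np.where(scores >= 0, 1, -1)


def accuracy(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Fraction of agreeing labels; codings {0,1} and {-1,+1} are unified."""
    predicted = to_pm1(predicted)
    actual = to_pm1(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual label vectors differ in length")
    return float(np.mean(predicted == actual))


@dataclass(frozen=True)
class BenchmarkClassifierSpec:
    """One of the four reference classifiers used in the filter benchmark.

    kinds: ``simple_tree`` (decision tree capped at 13 internal nodes),
    ``rbf_svm`` (RBF kernel, gamma = 1/m for m active features),
    ``linear_svm`` (C tuned by internal cross-validation),
    ``knn`` (k=4, Euclidean, unweighted, ties broken toward the nearest
    neighbour's label).
    """

    kind: str
    params: dict = field(default_factory=dict)

    _KINDS = ("simple_tree", "rbf_svm", "linear_svm", "knn")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; choose from {self._KINDS}")


class _TieAwareKNN:
    """kNN with majority vote; an exact tie goes to the nearest neighbour's label."""

    def __init__(self, k: int = 4):
        self.k = k
        self._nn = KNeighborsClassifier(n_neighbors=k, weights="uniform", metric="euclidean")

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_TieAwareKNN":
        self._y = np.asarray(y)
        self._nn.fit(X, self._y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        _, idx = self._nn.kneighbors(np.asarray(X, dtype=float))
        votes = self._y[idx]  # ordered nearest-first
        out = np.empty(len(votes), dtype=self._y.dtype)
        for i, row in enumerate(votes):
            vals, counts = np.unique(row, return_counts=True)
            top = vals[counts == counts.max()]
            out[i] = row[0] if len(top) > 1 else top[0]
        return out


def train_benchmark_classifier(
    spec: BenchmarkClassifierSpec, X: np.ndarray, y: np.ndarray
):
    """Fit the requested benchmark classifier with its reference settings."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    m = X.shape[1]
    if spec.kind == "simple_tree":
        # max 13 parent (internal) nodes == max 14 leaves in a binary tree
        limit = int(spec.params.get("max_parents", 13))
        clf = DecisionTreeClassifier(max_leaf_nodes=limit + 1, random_state=0)
    elif spec.kind == "rbf_svm":
        clf = SVC(kernel="rbf", gamma=spec.params.get("gamma", 1.0 / m), C=1.0)
    elif spec.kind == "linear_svm":
        grid = spec.params.get("C_grid", [0.01, 0.1, 1.0, 10.0, 100.0])
        clf = GridSearchCV(SVC(kernel="linear"), {"C": list(grid)}, cv=3)
    elif spec.kind == "knn":
        clf = _TieAwareKNN(k=int(spec.params.get("k", 4)))
    else:  # pragma: no cover - guarded by spec validation
        raise ValueError(spec.kind)
    clf.fit(X, y)
    return clf
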