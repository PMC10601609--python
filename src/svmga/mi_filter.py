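"""Mutual-information filter benchmark.

Feature relevance is scored by the mutual information (in bits) between
each discretized feature and the binary outcome, features are ranked weak
to strong, and subsets are chosen by a user threshold or a sequential
weakest-first elimination sweep that retrains a classifier at each retained
size m.  Everything is computed on the training split only, so the
benchmark is comparable with the wrapper method and leaks no test labels.

Continuous features are discretized by equal-frequency (quantile) binning
with a plug-in entropy estimate; features with few distinct values are
treated as categorical.  An exact k-nearest-neighbour MI estimator
(scikit-learn's) is available as an alternative backend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif

from .datasets import SplitDataset
from .svm import BenchmarkClassifierSpec, accuracy, train_benchmark_classifier

__all__ = [
    "RelevanceRanking",
    "SweepCurve",
    "mutual_information",
    "rank_features",
    "select_by_threshold",
    "sequential_elimination_sweep",
]

logger = logging.getLogger(__name__)


@dataclass
class RelevanceRanking:
    """Per-feature MI scores (bits) with the weak-to-strong order."""

    mi_values: np.ndarray
    order: np.ndarray  # feature indices, weakest first

    def __post_init__(self) -> None:
        self.mi_values = np.asarray(self.mi_values, dtype=float)
        self.order = np.asarray(self.order, dtype=int)
        if sorted(self.order) != list(range(len(self.mi_values))):
            raise ValueError("order must be a permutation of all feature indices")
        if (self.mi_values < -1e-12).any():
            raise ValueError("mutual information cannot be negative")

    def strongest(self, m: int) -> np.ndarray:
        """Indices of the m strongest features, ascending index order."""
        return np.sort(self.order[len(self.order) - m :])


@dataclass
class SweepCurve:
    """Accuracy trajectory of a sequential weakest-first elimination sweep."""

    classifier: str
    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.records, columns=["m", "train_acc", "test_acc", "overall_acc"])
        frame["classifier"] = self.classifier
        return frame


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin assignment; low-cardinality features stay categorical."""
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def mutual_information(
    feature: np.ndarray, labels: np.ndarray, n_bins: int = 8
) -> float:
    """Plug-in MI (bits) between a discretized feature and binary labels.

    A constant feature has zero MI; single-class labels are a contract
    violation.  0 <= MI <= min(H(binned feature), H(labels)).
    """
    x = np.asarray(feature, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if len(x) != len(y):
        raise ValueError("feature and label vectors differ in length")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; MI with the outcome is undefined")

    bins = _discretize(x, n_bins)
    joint = pd.crosstab(bins, y).to_numpy(dtype=float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def rank_features(
    X_train: np.ndarray,
    y_train: np.ndarray,
    n_bins: int = 8,
    backend: str = "binning",
) -> RelevanceRanking:
    """Rank features weak to strong by MI with the outcome.

    Ties break by ascending feature index.  ``backend="knn"`` swaps the
    binning estimator for scikit-learn's nearest-neighbour MI estimate
    (converted from nats to bits).
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train)
    if backend == "binning":
        mi = np.array([mutual_information(X[:, j], y, n_bins) for j in range(X.shape[1])])
    elif backend == "knn":
        mi = mutual_info_classif(X, y, random_state=0) / np.log(2)
    else:
        raise ValueError(f"unknown MI backend {backend!r}")
    # stable sort on MI => ties resolve by ascending feature index
    order = np.argsort(mi, kind="stable")
    return RelevanceRanking(mi_values=mi, order=order)


def select_by_threshold(ranking: RelevanceRanking, threshold: float) -> np.ndarray:
    """Boolean mask of features with MI >= threshold (may be all-False)."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return ranking.mi_values >= threshold


def sequential_elimination_sweep(
    split: SplitDataset,
    spec: BenchmarkClassifierSpec,
    step: int = 1,
    n_bins: int = 8,
    standardize: bool = True,
) -> SweepCurve:
    """Retrain the benchmark classifier while deleting weakest features.

    For m = d, d-step, ..., 1 the weakest-ranked features are dropped, the
    classifier is refit on the training split, and train / test / overall
    (all-sample) accuracies are recorded.  Ranking uses training data only.
    Failed refits are logged and skipped.
    """
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    ranking = rank_features(split.X_train, split.y_train, n_bins=n_bins)
    d = split.parent.n_features

    Xtr, ytr = split.X_train, split.y_train
    Xte, yte = split.X_test, split.y_test
    if standardize:
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        Xtr = (Xtr - mean) / sd
        Xte = (Xte - mean) / sd

    n_tr, n_te = len(ytr), len(yte)
    curve = SweepCurve(classifier=spec.kind)
    for m in range(d, 0, -step):
        keep = ranking.strongest(m)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf = train_benchmark_classifier(spec, Xtr[:, keep], ytr)
            train_acc = accuracy(clf.predict(Xtr[:, keep]), ytr)
            test_acc = accuracy(clf.predict(Xte[:, keep]), yte)
        except Exception as exc:  # per-point failure must not kill the sweep
            logger.warning("sweep point m=%d failed: %s", m, exc)
            continue
        overall = (train_acc * n_tr + test_acc * n_te) / (n_tr + n_te)
        curve.records.append(
            {"m": m, "train_acc": train_acc, "test_acc": test_acc, "overall_acc": overall}
        )
    return curve
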