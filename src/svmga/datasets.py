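"""Synthetic clinical-style cohorts and feature-table I/O.

The generator emulates the tabular structure of a small-sample,
high-dimensional clinical outcome study: two classes (outcome negative = 0,
positive = 1), many class-independent nuisance features, and a small planted
block of informative features whose class-conditional means differ by a
controllable effect size.  Both classes are drawn from class-conditional
multivariate Gaussians; the informative block may be equicorrelated.

Because the informative indices are known, generated cohorts double as
ground truth for feature-recovery experiments.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "FeatureDataset",
    "SplitDataset",
    "ConfigurationError",
    "DatasetFormatError",
    "DEFAULT_TRAIN_COUNTS",
    "generate_cohort",
    "stratified_split",
    "read_dataset",
    "write_dataset",
]

#: Per-class training counts of the reference cohort design
#: (38 training samples: 23 positive, 15 negative; 18 held out: 9/9).
DEFAULT_TRAIN_COUNTS: Mapping[int, int] = {1: 23, 0: 15}


class ConfigurationError(ValueError):
    """A generator or split configuration field is invalid."""


class DatasetFormatError(ValueError):
    """A feature table on disk violates the dataset contract."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the reference study design: 56 neonates, 248
    wavelet-derived features, 32 outcome-positive.

    Parameters
    ----------
    n_samples, n_features, n_positive, n_informative
        Cohort shape.  ``n_informative`` features receive a class-conditional
        mean shift; the rest are nuisance noise.
    effect_size
        Mean shift between classes on each informative feature, in units of
        the within-class standard deviation ``noise_sd``.
    noise_sd
        Within-class standard deviation of every feature.
    correlation
        Pairwise (equi-)correlation among the informative features, in
        ``[0, 1)``.  Nuisance features are always i.i.d.
    effect_direction
        ``"uniform"``: all informative shifts share one sign.
        ``"alternating"``: shifts alternate sign across the informative
        block, which, combined with positive ``correlation``, plants a
        multivariate signal whose marginal (per-feature) separation is much
        weaker than its joint separation.
    seed
        Seed of the generator; identical configs produce bit-identical
        cohorts.
    """

    n_samples: int = 56
    n_features: int = 248
    n_positive: int = 32
    n_informative: int = 5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    correlation: float = 0.0
    effect_direction: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_features", "n_positive", "n_informative"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be at least 2")
        if not 0 < self.n_positive < self.n_samples:
            raise ConfigurationError(
                f"n_positive must lie strictly between 0 and n_samples={self.n_samples}, "
                f"got {self.n_positive}"
            )
        if self.n_features < 1:
            raise ConfigurationError("n_features must be positive")
        if self.n_informative > self.n_features:
            raise ConfigurationError(
                f"n_informative={self.n_informative} exceeds n_features={self.n_features}"
            )
        if self.effect_size < 0:
            raise ConfigurationError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0 <= self.correlation < 1:
            raise ConfigurationError(f"correlation must be in [0, 1), got {self.correlation}")
        if self.effect_direction not in ("uniform", "alternating"):
            raise ConfigurationError(
                f"effect_direction must be 'uniform' or 'alternating', got {self.effect_direction!r}"
            )


@dataclass
class FeatureDataset:
    """A samples x features matrix with binary outcome labels.

    Labels are coded ``{0, 1}`` (outcome negative / positive) at the I/O
    boundary; the SVM layer maps them to ``{-1, +1}`` internally.
    ``informative_indices`` records the planted signal columns and is empty
    for external data.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    informative_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.informative_indices = np.asarray(self.informative_indices, dtype=int)
        if self.X.ndim != 2:
            raise DatasetFormatError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise DatasetFormatError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if np.isnan(self.X).any():
            raise DatasetFormatError("feature matrix contains missing values")
        labels = set(np.unique(self.y))
        if not labels <= {0, 1}:
            raise DatasetFormatError(f"labels must be binary 0/1, found values {sorted(labels)}")
        if labels != {0, 1}:
            raise DatasetFormatError("label vector must contain both classes")
        if len(self.feature_names) != self.X.shape[1]:
            raise DatasetFormatError("feature_names length does not match number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DatasetFormatError("feature names are not unique")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class SplitDataset:
    """A fixed train/test partition of a :class:`FeatureDataset`."""

    parent: FeatureDataset
    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        n = self.parent.n_samples
        union = np.concatenate([self.train_indices, self.test_indices])
        if len(np.unique(union)) != len(union):
            raise DatasetFormatError("train and test indices overlap")
        if sorted(union) != list(range(n)):
            raise DatasetFormatError("train and test indices must cover all samples")
        for name, idx in (("train", self.train_indices), ("test", self.test_indices)):
            if len(idx) == 0:
                raise DatasetFormatError(f"{name} split is empty")
            if len(np.unique(self.parent.y[idx])) < 2:
                raise DatasetFormatError(f"{name} split does not contain both classes")

    @property
    def X_train(self) -> np.ndarray:
        return self.parent.X[self.train_indices]

    @property
    def y_train(self) -> np.ndarray:
        return self.parent.y[self.train_indices]

    @property
    def X_test(self) -> np.ndarray:
        return self.parent.X[self.test_indices]

    @property
    def y_test(self) -> np.ndarray:
        return self.parent.y[self.test_indices]


def generate_cohort(config: GeneratorConfig = GeneratorConfig()) -> FeatureDataset:
    """Draw a seeded synthetic cohort from class-conditional Gaussians.

    Informative columns differ in class-conditional mean by
    ``effect_size * noise_sd``; nuisance columns are class-independent
    ``N(0, noise_sd**2)`` noise.  The informative block is equicorrelated at
    ``config.correlation`` via a shared Gaussian factor.
    """
    rng = np.random.default_rng(config.seed)
    n, d, k = config.n_samples, config.n_features, config.n_informative

    y = np.zeros(n, dtype=int)
    y[: config.n_positive] = 1
    rng.shuffle(y)

    informative = np.sort(rng.choice(d, size=k, replace=False))

    X = rng.normal(0.0, config.noise_sd, size=(n, d))
    if k > 0:
        rho = config.correlation
        if rho > 0:
            # equicorrelated block: shared factor + idiosyncratic part
            common = rng.normal(0.0, 1.0, size=(n, 1))
            idio = rng.normal(0.0, 1.0, size=(n, k))
            X[:, informative] = config.noise_sd * (
                np.sqrt(rho) * common + np.sqrt(1.0 - rho) * idio
            )
        signs = np.ones(k)
        if config.effect_direction == "alternating":
            signs[1::2] = -1.0
        shift = config.effect_size * config.noise_sd * signs
        X[np.ix_(y == 1, informative)] += shift

    names = [f"f{j:03d}" for j in range(d)]
    return FeatureDataset(X=X, y=y, feature_names=names, informative_indices=informative)


def stratified_split(
    dataset: FeatureDataset,
    train_counts: Mapping[int, int] = DEFAULT_TRAIN_COUNTS,
    seed: int = 0,
) -> SplitDataset:
    """Randomly assign exactly ``train_counts[label]`` samples of each class
    to the training split; the remainder form the test split.

    The default counts reproduce the reference design (train 38 = 23
    positive + 15 negative, test 18 = 9 + 9 on the 56-sample cohort).
    """
    rng = np.random.default_rng(seed)
    train: list[np.ndarray] = []
    for label in (0, 1):
        members = np.flatnonzero(dataset.y == label)
        want = int(train_counts.get(label, 0))
        if want > len(members):
            raise ConfigurationError(
                f"requested {want} training samples of class {label}, "
                f"but only {len(members)} exist"
            )
        train.append(rng.choice(members, size=want, replace=False))
    train_idx = np.sort(np.concatenate(train))
    test_idx = np.setdiff1d(np.arange(dataset.n_samples), train_idx)
    if len(test_idx) == 0:
        raise ConfigurationError("train counts consume every sample; test split would be empty")
    return SplitDataset(parent=dataset, train_indices=train_idx, test_indices=test_idx)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_dataset(
    dataset: FeatureDataset,
    path: str | Path,
    label_column: str = "pvl",
    config: GeneratorConfig | None = None,
) -> None:
    """Write a feature table as headed CSV plus a JSON metadata sidecar.

    The sidecar (``<path>.meta.json``) persists the informative indices and,
    when given, the generator config — everything needed to reproduce or
    score the cohort.
    """
    path = Path(path)
    frame = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    frame[label_column] = dataset.y
    frame.to_csv(path, index=False)

    meta: dict = {
        "label_column": label_column,
        "informative_indices": dataset.informative_indices.tolist(),
    }
    if config is not None:
        meta["generator"] = dataclasses.asdict(config)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_dataset(path: str | Path, label_column: str = "pvl") -> FeatureDataset:
    """Read a headed CSV feature table written by :func:`write_dataset`
    (or any delimited table with numeric features and a binary label column).

    Raises :class:`DatasetFormatError` with row/column context for missing
    values, non-binary labels, or duplicate feature names.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise DatasetFormatError(f"duplicate feature name {col!r}")
        seen.add(col)
    frame = pd.read_csv(path, float_precision="round_trip")
    if label_column not in frame.columns:
        raise DatasetFormatError(f"label column {label_column!r} not found in {path}")
    labels = frame[label_column]
    bad = labels[~labels.isin([0, 1])]
    if len(bad):
        raise DatasetFormatError(
            f"label column {label_column!r} must be binary 0/1; "
            f"row {bad.index[0]} has value {bad.iloc[0]!r}"
        )
    features = frame.drop(columns=[label_column])
    na = features.isna()
    if na.any().any():
        col = na.any()[na.any()].index[0]
        row = na[col][na[col]].index[0]
        raise DatasetFormatError(f"missing value at row {row}, column {col!r}")
    try:
        X = features.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DatasetFormatError(f"non-numeric feature value in {path}: {exc}") from exc

    informative: Sequence[int] = []
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        informative = json.loads(sidecar.read_text()).get("informative_indices", [])
    return FeatureDataset(
        X=X,
        y=labels.to_numpy(dtype=int),
        feature_names=list(features.columns),
        informative_indices=np.asarray(informative, dtype=int),
    )
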