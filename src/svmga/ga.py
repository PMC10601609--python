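"""Embedded genetic-algorithm feature selection for a linear SVM.

Candidate feature subsets are binary chromosomes over the d features.  Each
chromosome is scored by training a linear SVM on the training split
restricted to its active features and evaluating a three-term fitness
function, minimized by the GA:

    FF  = FF1 + FF2 + FF3
    FF1 = 1 / ACC_train            (training accuracy term)
    FF2 = a * m / d                (cardinality penalty; m active features)
    FF3 = b / width                (margin term; width = 2 / ||w||_2)

so a perfectly accurate model with a = b = 0 settles at FF = 1.  FF3
rewards subsets with a wide separating margin, steering the search toward
generalization without ever touching the test split — the fitness function
reads the training partition only, by construction.  Per epoch the best
chromosome's SVM is additionally evaluated on the held-out test split for
monitoring; that evaluation feeds nothing back into the search.

Two historical variants of the penalty terms are selectable: ``ff2_form=
"literal_reciprocal"`` scores FF2 = a / m (decreasing in m), and
``ff3_form="reciprocal_weight_norm"`` scores FF3 = b / ||w||_2 (the
weight-vector norm instead of the geometric width).  The defaults implement
the declared objectives: minimize cardinality, maximize margin.

The generational loop uses roulette selection with probability
proportional to 1 / FF (a minimization transform), single-point crossover,
independent bit-flip mutation with empty-mask repair, and elitism.  The
whole trajectory is a pure function of (dataset, config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datasets import SplitDataset
from .svm import SVMModel, accuracy, predict, to_pm1, train_linear_svm

__all__ = [
    "FeatureSubset",
    "GAConfig",
    "FitnessBreakdown",
    "TrajectoryRecord",
    "GAResult",
    "evaluate_fitness",
    "roulette_select",
    "rank_select",
    "reproduce",
    "mutate",
    "run_ga",
    "monitor_epoch",
]

logger = logging.getLogger(__name__)

_FALLBACK_PENALTY = 1e6


@dataclass(frozen=True)
class FeatureSubset:
    """A candidate feature subset encoded as a binary inclusion mask."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def m(self) -> int:
        """Number of active features (the subset cardinality)."""
        return int(self.mask.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @classmethod
    def from_indices(cls, indices: Sequence[int], d: int) -> "FeatureSubset":
        mask = np.zeros(d, dtype=bool)
        mask[np.asarray(indices, dtype=int)] = True
        return cls(mask)


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the embedded GA.

    ``n_chromosomes=1200`` and ``max_generations=1005`` with crossover 0.8
    and mutation 0.01 are the full-scale reference settings; desk-scale
    experiments shrink the first two.  ``a`` and ``b`` weight the
    cardinality and margin terms (defaults 0.05 each keep FF2+FF3 well
    below FF1 at convergence).  ``target_ff`` optionally stops the run once
    the best fitness reaches it.
    """

    n_chromosomes: int = 1200
    max_generations: int = 1005
    crossover_rate: float = 0.8
    mutation_rate: float = 0.01
    a: float = 0.05
    b: float = 0.05
    C: float = 1.0
    seed: int = 0
    elitism: int = 1
    ff2_form: str = "normalized_cardinality"
    ff3_form: str = "reciprocal_margin_width"
    selection: str = "roulette"
    init_density: float = 0.5
    standardize: bool = True
    target_ff: float | None = None
    penalty_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 2:
            raise ValueError("n_chromosomes must be at least 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be at least 1")
        for name in ("crossover_rate", "mutation_rate", "init_density"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.a < 0 or self.b < 0:
            raise ValueError("fitness weights a and b must be non-negative")
        if self.elitism < 0 or self.elitism >= self.n_chromosomes:
            raise ValueError("elitism must be in [0, n_chromosomes)")
        if self.ff2_form not in ("normalized_cardinality", "literal_reciprocal"):
            raise ValueError(f"unknown ff2_form {self.ff2_form!r}")
        if self.ff3_form not in ("reciprocal_margin_width", "reciprocal_weight_norm"):
            raise ValueError(f"unknown ff3_form {self.ff3_form!r}")
        if self.selection not in ("roulette", "rank"):
            raise ValueError(f"unknown selection {self.selection!r}")


@dataclass(frozen=True)
class FitnessBreakdown:
    """The three fitness terms of one chromosome, plus their ingredients.

    Degenerate evaluations (zero training accuracy or a zero weight
    vector) carry ``ff_total = inf``; the GA replaces them with a finite
    per-generation penalty so selection never sees an infinity.
    """

    ff1: float
    ff2: float
    ff3: float
    ff_total: float
    acc_train: float
    m: int
    margin: float
    degenerate: bool = False


@dataclass(frozen=True)
class TrajectoryRecord:
    """Per-epoch monitoring snapshot: best fitness, accuracies, dimensionality."""

    epoch: int
    best_ff: float
    train_acc: float
    test_acc: float
    overall_acc: float
    m_best: int


@dataclass
class GAResult:
    best_subset: FeatureSubset
    best_model: SVMModel
    best_fitness: FitnessBreakdown
    trajectory: list[TrajectoryRecord]
    n_evaluations: int = 0


def _fit_subset(
    subset: FeatureSubset, X_train: np.ndarray, y_train: np.ndarray, config: GAConfig
) -> SVMModel:
    model = train_linear_svm(
        X_train[:, subset.mask], y_train, C=config.C, standardize=config.standardize
    )
    model.feature_subset = subset.indices
    return model


def _breakdown(
    subset: FeatureSubset, model: SVMModel, acc_train: float, d: int, config: GAConfig
) -> FitnessBreakdown:
    m = subset.m
    ff1 = 1.0 / acc_train if acc_train > 0 else math.inf
    ff2 = config.a * (m / d) if config.ff2_form == "normalized_cardinality" else config.a / m
    w_norm = float(np.linalg.norm(model.w))
    margin = model.margin_width
    degenerate = model.degenerate or acc_train <= 0
    if config.ff3_form == "reciprocal_margin_width":
        ff3 = config.b / margin if math.isfinite(margin) else math.inf
    else:
        ff3 = config.b / w_norm if w_norm > 0 else math.inf
    if config.b == 0:
        ff3 = 0.0  # margin term switched off; zero-w degeneracy still flagged
    total = ff1 + ff2 + ff3 if not degenerate else math.inf
    if degenerate:
        logger.debug("degenerate evaluation: m=%d acc=%.3f", m, acc_train)
    return FitnessBreakdown(
        ff1=ff1,
        ff2=ff2,
        ff3=ff3,
        ff_total=total,
        acc_train=acc_train,
        m=m,
        margin=margin,
        degenerate=degenerate,
    )


def evaluate_fitness(
    subset: FeatureSubset,
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: GAConfig,
) -> FitnessBreakdown:
    """Score one feature subset on the training partition only.

    Trains a linear SVM on the training rows restricted to the subset and
    assembles FF1 + FF2 + FF3.  Only the training partition is accepted:
    test rows are structurally out of reach of the fitness.
    """
    if subset.m < 1:
        raise ValueError("cannot evaluate an empty feature subset")
    model = _fit_subset(subset, X_train, y_train, config)
    acc = accuracy(predict(model, X_train[:, subset.mask]), y_train)
    d = X_train.shape[1]
    return _breakdown(subset, model, acc, d, config)


def roulette_select(
    population: Sequence[FeatureSubset],
    fitness_scores: Sequence[float],
    rng: np.random.Generator,
) -> FeatureSubset:
    """Draw one chromosome with probability proportional to 1 / fitness.

    The reciprocal transform turns the minimized fitness into a selection
    weight: lower FF, higher chance.
    """
    if len(population) == 0:
        raise ValueError("cannot select from an empty population")
    scores = np.asarray(fitness_scores, dtype=float)
    if not np.all(np.isfinite(scores)) or np.any(scores <= 0):
        raise ValueError("fitness scores must be finite and positive for roulette selection")
    weights = 1.0 / scores
    probs = weights / weights.sum()
    return population[int(rng.choice(len(population), p=probs))]


def rank_select(
    population: Sequence[FeatureSubset],
    fitness_scores: Sequence[float],
    rng: np.random.Generator,
) -> FeatureSubset:
    """Linear rank-based selection (best rank gets the largest weight)."""
    if len(population) == 0:
        raise ValueError("cannot select from an empty population")
    order = np.argsort(np.asarray(fitness_scores, dtype=float), kind="stable")
    n = len(population)
    weights = np.empty(n)
    weights[order] = np.arange(n, 0, -1)  # best fitness -> weight n
    probs = weights / weights.sum()
    return population[int(rng.choice(n, p=probs))]


def reproduce(
    x: FeatureSubset, y: FeatureSubset, config: GAConfig, rng: np.random.Generator
) -> FeatureSubset:
    """Single-point crossover with probability ``crossover_rate``, else copy x.

    The locus l is uniform on 1..d-1; the child takes x's first l bits and
    y's remainder.
    """
    if x.mask.shape != y.mask.shape:
        raise ValueError("parent chromosomes differ in length")
    d = len(x.mask)
    if rng.random() < config.crossover_rate and d > 1:
        locus = int(rng.integers(1, d))
        child = np.concatenate([x.mask[:locus], y.mask[locus:]])
        return FeatureSubset(child)
    return FeatureSubset(x.mask.copy())


def mutate(
    subset: FeatureSubset, mutation_rate: float, rng: np.random.Generator
) -> FeatureSubset:
    """Flip each bit independently with ``mutation_rate``; repair empty masks.

    If every bit ends up off, one uniformly chosen bit is switched on so the
    chromosome stays evaluable.
    """
    mask = subset.mask.copy()
    flips = rng.random(len(mask)) < mutation_rate
    mask ^= flips
    if not mask.any():
        mask[int(rng.integers(len(mask)))] = True
    return FeatureSubset(mask)


def monitor_epoch(
    best_model: SVMModel,
    best_subset: FeatureSubset,
    best_ff: float,
    split: SplitDataset,
    epoch: int,
) -> TrajectoryRecord:
    """Evaluate the epoch's best SVM on train, test and all samples.

    Pure monitoring: the record is appended to the trajectory and nothing
    flows back into the GA state.
    """
    cols = best_subset.mask
    y_train = to_pm1(split.y_train)
    y_test = to_pm1(split.y_test)
    train_acc = accuracy(predict(best_model, split.X_train[:, cols]), y_train)
    test_acc = accuracy(predict(best_model, split.X_test[:, cols]), y_test)
    n_tr, n_te = len(y_train), len(y_test)
    overall = (train_acc * n_tr + test_acc * n_te) / (n_tr + n_te)
    return TrajectoryRecord(
        epoch=epoch,
        best_ff=best_ff,
        train_acc=train_acc,
        test_acc=test_acc,
        overall_acc=overall,
        m_best=best_subset.m,
    )


def _init_population(d: int, config: GAConfig, rng: np.random.Generator) -> list[FeatureSubset]:
    pop = []
    for _ in range(config.n_chromosomes):
        mask = rng.random(d) < config.init_density
        if not mask.any():
            mask[int(rng.integers(d))] = True
        pop.append(FeatureSubset(mask))
    return pop


def run_ga(split: SplitDataset, config: GAConfig) -> GAResult:
    """Run the embedded GA feature search on a fixed train/test split.

    Generational loop with elitism: per generation every chromosome is
    scored by :func:`evaluate_fitness` on the training partition (scores
    are memoized per mask — the fitness is a pure function of the mask),
    degenerate scores are replaced by ``penalty_factor`` times the worst
    finite score of the generation, parents are drawn by the configured
    selection scheme, and children are produced by crossover + mutation.
    The best chromosome's SVM is evaluated on the test split once per epoch
    for the trajectory only.  Stops at ``max_generations`` or when the best
    fitness reaches ``target_ff``.
    """
    rng = np.random.default_rng(config.seed)
    X_train = split.X_train
    y_train = to_pm1(split.y_train)
    d = split.parent.n_features

    cache: dict[bytes, FitnessBreakdown] = {}
    model_cache: dict[bytes, SVMModel] = {}
    n_evaluations = 0

    def score(subset: FeatureSubset) -> FitnessBreakdown:
        nonlocal n_evaluations
        key = np.packbits(subset.mask).tobytes()
        hit = cache.get(key)
        if hit is None:
            n_evaluations += 1
            hit = evaluate_fitness(subset, X_train, y_train, config)
            cache[key] = hit
        return hit

    def model_for(subset: FeatureSubset) -> SVMModel:
        key = np.packbits(subset.mask).tobytes()
        hit = model_cache.get(key)
        if hit is None:
            hit = _fit_subset(subset, X_train, y_train, config)
            model_cache.clear()  # only the current best is worth keeping
            model_cache[key] = hit
        return hit

    select = roulette_select if config.selection == "roulette" else rank_select

    population = _init_population(d, config, rng)
    trajectory: list[TrajectoryRecord] = []
    best_subset: FeatureSubset | None = None
    best_fitness: FitnessBreakdown | None = None

    for epoch in range(1, config.max_generations + 1):
        breakdowns = [score(c) for c in population]
        raw = np.array([b.ff_total for b in breakdowns])
        finite = raw[np.isfinite(raw)]
        penalty = (
            config.penalty_factor * finite.max() if len(finite) else _FALLBACK_PENALTY
        )
        effective = np.where(np.isfinite(raw), raw, penalty)

        gen_best = int(np.argmin(effective))
        if best_fitness is None or effective[gen_best] < best_fitness.ff_total:
            best_subset = population[gen_best]
            bd = breakdowns[gen_best]
            best_fitness = bd if math.isfinite(bd.ff_total) else replace(
                bd, ff_total=float(effective[gen_best])
            )

        trajectory.append(
            monitor_epoch(model_for(best_subset), best_subset, best_fitness.ff_total, split, epoch)
        )
        logger.info(
            "epoch %d: best_ff=%.6f m=%d train_acc=%.3f",
            epoch,
            best_fitness.ff_total,
            best_fitness.m,
            best_fitness.acc_train,
        )

        if config.target_ff is not None and best_fitness.ff_total <= config.target_ff:
            break
        if epoch == config.max_generations:
            break

        new_population: list[FeatureSubset] = [
            FeatureSubset(best_subset.mask.copy()) for _ in range(config.elitism)
        ]
        while len(new_population) < config.n_chromosomes:
            parent_x = select(population, effective, rng)
            parent_y = select(population, effective, rng)
            child = reproduce(parent_x, parent_y, config, rng)
            child = mutate(child, config.mutation_rate, rng)
            new_population.append(child)
        population = new_population

    assert best_subset is not None and best_fitness is not None
    return GAResult(
        best_subset=best_subset,
        best_model=model_for(best_subset),
        best_fitness=best_fitness,
        trajectory=trajectory,
        n_evaluations=n_evaluations,
    )
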