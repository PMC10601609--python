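"""GA operators, fitness arithmetic, and the embedded search loop."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import svmga
from helpers import enumerate_best_subset
from svmga.datasets import FeatureDataset, SplitDataset
from svmga.ga import FeatureSubset, _breakdown, monitor_epoch
from svmga.svm import SVMModel


class ScriptedRng:
    """Minimal rng stand-in with queued outputs, for operator-level tests."""

    def __init__(self, randoms=(), integers=()):
        self._randoms = list(randoms)
        self._integers = list(integers)

    def random(self, size=None):
        if size is None:
            return self._randoms.pop(0)
        return np.array([self._randoms.pop(0) for _ in range(size)])

    def integers(self, lo, hi=None):
        return self._integers.pop(0)


def _stub_model(w):
    w = np.asarray(w, dtype=float)
    return SVMModel(
        alphas=np.zeros(2), support_indices=np.arange(2), w=w, bias=0.0, C=1.0,
        degenerate=bool(np.linalg.norm(w) < 1e-10),
    )


def _toy_split(d=4, n_train_pairs=4, n_test_pairs=2, seed=0):
    """Separable toy: one signal column among d, small split."""
    rng = np.random.default_rng(seed)
    n = 2 * (n_train_pairs + n_test_pairs)
    y = np.tile([1, 0], n // 2)
    X = rng.normal(size=(n, d))
    X[:, 0] = np.where(y == 1, 3.0, -3.0) + 0.1 * rng.normal(size=n)
    ds = FeatureDataset(X=X, y=y, feature_names=[f"f{i}" for i in range(d)])
    train = np.arange(2 * n_train_pairs)
    test = np.arange(2 * n_train_pairs, n)
    return SplitDataset(parent=ds, train_indices=train, test_indices=test)


class TestFitnessArithmetic:
    def test_perfect_accuracy_settles_at_one_with_zero_weights(self):
        split = _toy_split()
        config = svmga.GAConfig(n_chromosomes=4, a=0.0, b=0.0, seed=0)
        subset = FeatureSubset.from_indices([0], d=4)
        bd = svmga.evaluate_fitness(subset, split.X_train, split.y_train, config)
        assert bd.acc_train == 1.0
        assert bd.ff_total == pytest.approx(1.0)
        assert (bd.ff1, bd.ff2, bd.ff3) == (1.0, 0.0, 0.0)

    def test_half_accuracy_doubles_ff1(self):
        config = svmga.GAConfig(n_chromosomes=4, a=0.0, b=0.0)
        bd = _breakdown(
            FeatureSubset.from_indices([0], d=4), _stub_model([1.0]), 0.5, 4, config
        )
        assert bd.ff_total == pytest.approx(2.0)

    def test_default_forms_sum_terms(self):
        # acc=1, a=b=0.1, m=10, d=100, margin=2 (|w|=1) -> 1 + 0.01 + 0.05
        config = svmga.GAConfig(n_chromosomes=4, a=0.1, b=0.1)
        bd = _breakdown(
            FeatureSubset.from_indices(range(10), d=100), _stub_model([1.0]), 1.0, 100, config
        )
        assert bd.ff1 == pytest.approx(1.0)
        assert bd.ff2 == pytest.approx(0.01)
        assert bd.ff3 == pytest.approx(0.05)
        assert bd.ff_total == pytest.approx(1.06)

    def test_literal_forms_match_their_formulas(self):
        config = svmga.GAConfig(
            n_chromosomes=4, a=0.1, b=0.1,
            ff2_form="literal_reciprocal", ff3_form="reciprocal_weight_norm",
        )
        bd = _breakdown(
            FeatureSubset.from_indices(range(10), d=100), _stub_model([2.0]), 1.0, 100, config
        )
        assert bd.ff2 == pytest.approx(0.1 / 10)
        assert bd.ff3 == pytest.approx(0.1 / 2.0)

    def test_degenerate_zero_weight_flagged_infinite(self):
        split = _toy_split()
        X = split.X_train.copy()
        X[:, 2] = 5.0  # constant column
        config = svmga.GAConfig(n_chromosomes=4, a=0.05, b=0.05)
        bd = svmga.evaluate_fitness(
            FeatureSubset.from_indices([2], d=4), X, split.y_train, config
        )
        assert bd.degenerate
        assert math.isinf(bd.ff_total)

    def test_empty_subset_rejected(self):
        split = _toy_split()
        config = svmga.GAConfig(n_chromosomes=4)
        with pytest.raises(ValueError, match="empty"):
            svmga.evaluate_fitness(
                FeatureSubset(np.zeros(4, dtype=bool)), split.X_train, split.y_train, config
            )


class TestSelection:
    def test_probabilities_follow_reciprocal_fitness(self):
        pop = [FeatureSubset.from_indices([0], 2), FeatureSubset.from_indices([1], 2)]
        rng = np.random.default_rng(0)
        draws = sum(
            svmga.roulette_select(pop, [1.0, 3.0], rng).indices[0] == 0
            for _ in range(100_000)
        )
        # weights 1 and 1/3 -> P(first) = 0.75
        assert draws / 100_000 == pytest.approx(0.75, abs=0.01)

    def test_equal_scores_select_uniformly(self):
        pop = [FeatureSubset.from_indices([0], 2), FeatureSubset.from_indices([1], 2)]
        rng = np.random.default_rng(1)
        draws = sum(
            svmga.roulette_select(pop, [2.0, 2.0], rng).indices[0] == 0
            for _ in range(20_000)
        )
        assert draws / 20_000 == pytest.approx(0.5, abs=0.02)

    def test_single_chromosome_always_returned(self):
        pop = [FeatureSubset.from_indices([1], 3)]
        out = svmga.roulette_select(pop, [1.7], np.random.default_rng(0))
        assert np.array_equal(out.mask, pop[0].mask)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            svmga.roulette_select([], [], np.random.default_rng(0))

    def test_nonfinite_scores_rejected(self):
        pop = [FeatureSubset.from_indices([0], 2)] * 2
        with pytest.raises(ValueError, match="finite"):
            svmga.roulette_select(pop, [1.0, math.inf], np.random.default_rng(0))


class TestReproduceMutate:
    def test_single_point_crossover_at_locus(self):
        x = FeatureSubset(np.array([1, 1, 1, 1], dtype=bool))
        y = FeatureSubset(np.array([0, 0, 0, 0], dtype=bool))
        config = svmga.GAConfig(n_chromosomes=4, crossover_rate=0.8)
        child = svmga.reproduce(x, y, config, ScriptedRng(randoms=[0.0], integers=[2]))
        assert child.mask.astype(int).tolist() == [1, 1, 0, 0]

    @given(locus=st.integers(1, 7))
    def test_identical_parents_reproduce_identically(self, locus):
        x = FeatureSubset(np.array([1, 0, 1, 0, 1, 1, 0, 1], dtype=bool))
        config = svmga.GAConfig(n_chromosomes=4, crossover_rate=1.0)
        child = svmga.reproduce(x, x, config, ScriptedRng(randoms=[0.0], integers=[locus]))
        assert np.array_equal(child.mask, x.mask)

    def test_zero_crossover_rate_copies_first_parent(self):
        rng = np.random.default_rng(0)
        x = FeatureSubset(np.array([1, 0, 1], dtype=bool))
        y = FeatureSubset(np.array([0, 1, 0], dtype=bool))
        config = svmga.GAConfig(n_chromosomes=4, crossover_rate=0.0)
        for _ in range(5):
            assert np.array_equal(svmga.reproduce(x, y, config, rng).mask, x.mask)

    def test_length_mismatch_rejected(self):
        config = svmga.GAConfig(n_chromosomes=4)
        with pytest.raises(ValueError, match="length"):
            svmga.reproduce(
                FeatureSubset(np.ones(3, dtype=bool)),
                FeatureSubset(np.ones(4, dtype=bool)),
                config,
                np.random.default_rng(0),
            )

    def test_zero_rate_is_identity(self):
        mask = np.array([1, 0, 1, 1], dtype=bool)
        out = svmga.mutate(FeatureSubset(mask), 0.0, np.random.default_rng(0))
        assert np.array_equal(out.mask, mask)

    def test_full_rate_flips_every_bit(self):
        out = svmga.mutate(
            FeatureSubset(np.array([1, 0, 1, 0], dtype=bool)), 1.0, np.random.default_rng(0)
        )
        assert out.mask.astype(int).tolist() == [0, 1, 0, 1]

    def test_all_zero_result_repaired(self):
        out = svmga.mutate(FeatureSubset(np.array([True])), 1.0, np.random.default_rng(0))
        assert out.m == 1

    def test_expected_flip_count_matches_binomial(self):
        rng = np.random.default_rng(2)
        base = FeatureSubset(np.zeros(248, dtype=bool) | (np.arange(248) < 124))
        flips = [
            int(np.sum(svmga.mutate(base, 0.01, rng).mask ^ base.mask)) for _ in range(10_000)
        ]
        assert np.mean(flips) == pytest.approx(2.48, abs=0.1)


class TestMonitor:
    def test_counting_with_reference_split_sizes(self):
        # 56 samples, 38 train / 18 test; model predicts sign of the single feature
        y = np.tile([1, 0], 28)
        v = np.where(y == 1, 1.0, -1.0)
        flip = np.arange(38, 44)  # 6 test rows made wrong -> 12/18 correct
        v[flip] = -v[flip]
        ds = FeatureDataset(X=v[:, None], y=y, feature_names=["f0"])
        split = SplitDataset(
            parent=ds, train_indices=np.arange(38), test_indices=np.arange(38, 56)
        )
        rec = monitor_epoch(
            _stub_model([1.0]), FeatureSubset.from_indices([0], 1), 1.0, split, epoch=3
        )
        assert rec.train_acc == 1.0
        assert rec.test_acc == pytest.approx(12 / 18)
        assert rec.overall_acc == pytest.approx(50 / 56)
        assert rec.epoch == 3

    def test_perfect_epoch_reports_ones(self):
        split = _toy_split()
        model = svmga.train_linear_svm(
            split.X_train[:, [0]], svmga.to_pm1(split.y_train), standardize=True
        )
        rec = monitor_epoch(model, FeatureSubset.from_indices([0], 4), 1.0, split, epoch=1)
        assert rec.train_acc == rec.test_acc == rec.overall_acc == 1.0


class TestRunGA:
    def test_matches_exhaustive_enumeration(self):
        ds = svmga.generate_cohort(
            svmga.GeneratorConfig(
                n_samples=30, n_features=6, n_positive=16, n_informative=2,
                effect_size=4.0, seed=5,
            )
        )
        split = svmga.stratified_split(ds, {1: 11, 0: 9}, seed=5)
        config = svmga.GAConfig(n_chromosomes=32, max_generations=25, seed=5)
        _, oracle_ff = enumerate_best_subset(split.X_train, svmga.to_pm1(split.y_train), config)
        result = svmga.run_ga(split, config)
        assert result.best_fitness.ff_total == pytest.approx(oracle_ff, abs=1e-10)

    def test_trajectory_is_reproducible(self):
        split = _toy_split(d=12, n_train_pairs=8, n_test_pairs=4, seed=3)
        config = svmga.GAConfig(n_chromosomes=20, max_generations=8, seed=9)
        a = svmga.run_ga(split, config)
        b = svmga.run_ga(split, config)
        assert a.trajectory == b.trajectory
        assert np.array_equal(a.best_subset.mask, b.best_subset.mask)

    def test_best_fitness_monotone_under_elitism(self):
        split = _toy_split(d=15, n_train_pairs=8, n_test_pairs=4, seed=4)
        config = svmga.GAConfig(n_chromosomes=20, max_generations=12, seed=2, elitism=1)
        result = svmga.run_ga(split, config)
        ffs = [r.best_ff for r in result.trajectory]
        assert all(b <= a + 1e-12 for a, b in zip(ffs, ffs[1:]))
        assert all(map(math.isfinite, ffs))

    def test_overall_accuracy_is_weighted_mean(self):
        split = _toy_split(d=10, n_train_pairs=8, n_test_pairs=4, seed=6)
        result = svmga.run_ga(split, svmga.GAConfig(n_chromosomes=16, max_generations=5, seed=1))
        n_tr, n_te = 16, 8
        for rec in result.trajectory:
            expected = (rec.train_acc * n_tr + rec.test_acc * n_te) / (n_tr + n_te)
            assert rec.overall_acc == pytest.approx(expected)

    def test_target_ff_stops_early(self):
        split = _toy_split(d=6)
        config = svmga.GAConfig(
            n_chromosomes=16, max_generations=50, seed=0, a=0.0, b=0.0, target_ff=1.0
        )
        result = svmga.run_ga(split, config)
        assert result.trajectory[-1].best_ff <= 1.0
        assert len(result.trajectory) < 50

    def test_fitness_is_blind_to_test_labels(self):
        split = _toy_split(d=10, n_train_pairs=8, n_test_pairs=4, seed=8)
        poisoned_parent = FeatureDataset(
            X=split.parent.X.copy(),
            y=split.parent.y.copy(),
            feature_names=list(split.parent.feature_names),
        )
        poisoned_parent.y[split.test_indices] = 1 - poisoned_parent.y[split.test_indices]
        poisoned = SplitDataset(
            parent=poisoned_parent,
            train_indices=split.train_indices,
            test_indices=split.test_indices,
        )
        config = svmga.GAConfig(n_chromosomes=20, max_generations=6, seed=3)
        a = svmga.run_ga(split, config)
        b = svmga.run_ga(poisoned, config)
        assert [r.best_ff for r in a.trajectory] == [r.best_ff for r in b.trajectory]
        assert [r.m_best for r in a.trajectory] == [r.m_best for r in b.trajectory]
        assert np.array_equal(a.best_subset.mask, b.best_subset.mask)

    def test_survives_constant_column(self):
        split = _toy_split(d=5, seed=2)
        parent = split.parent
        parent.X[:, 3] = 1.0
        config = svmga.GAConfig(n_chromosomes=12, max_generations=5, seed=0)
        result = svmga.run_ga(split, config)
        assert math.isfinite(result.best_fitness.ff_total)
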