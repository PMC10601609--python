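import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import svmga

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort() -> svmga.FeatureDataset:
    """Reference-shaped cohort: 56 samples x 248 features, 32 positive."""
    return svmga.generate_cohort(svmga.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def planted_cohort() -> svmga.FeatureDataset:
    """Small cohort with a strong planted signal: 5 informative of 60, effect 6 sd."""
    return svmga.generate_cohort(
        svmga.GeneratorConfig(
            n_samples=56, n_features=60, n_positive=32,
            n_informative=5, effect_size=6.0, seed=1,
        )
    )


@pytest.fixture(scope="session")
def planted_split(planted_cohort) -> svmga.SplitDataset:
    return svmga.stratified_split(planted_cohort, seed=1)


@pytest.fixture(scope="session")
def separable_2d():
    """A well-separated random 2-D two-class point set (n=20)."""
    rng = np.random.default_rng(7)
    pos = rng.normal([2.5, 2.0], 0.5, size=(10, 2))
    neg = rng.normal([-2.0, -2.5], 0.5, size=(10, 2))
    X = np.vstack([pos, neg])
    y = np.array([1] * 10 + [-1] * 10)
    return X, y
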