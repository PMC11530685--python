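import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "sportfs",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("sportfs")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-participant cohort with the default planted structure."""
    from sportfs.datagen import GeneratorSpec, generate_dataset

    return generate_dataset(GeneratorSpec(n_participants=400, seed=7))


@pytest.fixture(scope="session")
def small_forest(small_cohort):
    from sportfs.forest import WeightedRandomForestClassifier

    return WeightedRandomForestClassifier(
        n_trees=25, max_depth=12, random_state=11
    ).fit(small_cohort.features, small_cohort.labels.to_numpy())
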