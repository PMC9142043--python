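import numpy as np
import pytest

from fabrycars import (
    build_axis,
    default_configs,
    image_mean_spectrum,
    preprocess,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def axis33():
    """The 33-channel CH-stretch acquisition axis."""
    return build_axis()


def cohort_features(config):
    """Simulate a cohort and return per-image mean-spectrum features."""
    _, cubes = simulate_cohort(config)
    return [image_mean_spectrum(preprocess(c)) for c in cubes]


@pytest.fixture(scope="session")
def dataset3_cohort():
    """One Dataset-III-analogue cohort (8 WT / 10 KO mice, one image each)."""
    config = default_configs(seed=7)[0]
    manifest, cubes = simulate_cohort(config)
    return config, manifest, cubes


@pytest.fixture(scope="session")
def dataset3_matrices(dataset3_cohort):
    _, _, cubes = dataset3_cohort
    return [preprocess(c) for c in cubes]


@pytest.fixture(scope="session")
def dataset3_features(dataset3_matrices):
    return [image_mean_spectrum(m) for m in dataset3_matrices]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
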