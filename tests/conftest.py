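import numpy as np
import pytest

from odorspec import (NetworkArchitecture, SyntheticSpec, TrainingConfig,
                      generate_dataset)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size synthetic dataset at the study conditions (seed 0)."""
    return generate_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset (28 oils) for fast training-path tests."""
    return generate_dataset(SyntheticSpec(n_oils=28, seed=1))


@pytest.fixture
def small_arch():
    return NetworkArchitecture(ae_hidden=12, bottleneck=5, map_hidden1=8,
                               map_hidden2=4, n_groups=3)


@pytest.fixture
def fast_config():
    return TrainingConfig(epochs_ae=80, epochs_map=80, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
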