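import warnings

import numpy as np
import pytest

from reachdyn.arm_model import build_default_arm_model
from reachdyn.dataset import split_dataset
from reachdyn.pipeline import derive_seed, generate_corpus, reduced_gru_experiment
from reachdyn.trajectory import build_workspace_grid


@pytest.fixture(scope="session")
def arm_model():
    return build_default_arm_model()


@pytest.fixture(scope="session")
def grid(arm_model):
    return build_workspace_grid(arm_model)


@pytest.fixture(scope="session")
def small_corpus():
    """Four-vertex corpus (12 movements, two durations): cheap enough for
    unit tests of datasets, dynamics consistency and evaluation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = generate_corpus(grid_shape="2x1x2", durations=(0.5, 1.0))
    return ds


@pytest.fixture(scope="session")
def split_small_corpus(small_corpus):
    return split_dataset(small_corpus, seed=derive_seed(7, "split"))


@pytest.fixture(scope="session")
def gru_experiment():
    """The reduced-scale trained GRU study (corner subgrid, 0.5/1.0 s).

    Built once per session; used by the surrogate-accuracy and
    noise-robustness acceptance checks.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reduced_gru_experiment(seed=1, noise_fractions=(0.01, 0.05))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
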