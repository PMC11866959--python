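import numpy as np
import pytest

from ionsaxs.ionnet import Hyperparameters, train
from ionsaxs.saxs import default_q_grid
from ionsaxs.structures import assign_accessibility
from ionsaxs.synthetic import make_helix, make_neighborhoods


@pytest.fixture(scope="session")
def q_grid():
    return default_q_grid(0.4, 81)


@pytest.fixture(scope="session")
def helix():
    return make_helix(10)


@pytest.fixture(scope="session")
def helix_acc(helix):
    return assign_accessibility(helix)


@pytest.fixture(scope="session")
def small_training_result():
    """A quickly trained classifier shared across classifier/pipeline tests."""
    data = make_neighborhoods(300, 300, seed=0)
    return train(data, folds=2, seed=0, hyper=Hyperparameters(epochs=30, seed=0))


@pytest.fixture(scope="session")
def classifier(small_training_result):
    return small_training_result.model
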