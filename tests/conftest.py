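import numpy as np
import pytest

from msiscreen import (
    DEFAULT_PANEL,
    Call,
    MarkerDef,
    simulate_training_set,
    train_classifier,
)

TRAIN_SEED = 20260101
TRAIN_DEPTH = 2000
TRAIN_N_PER_CLASS = 100


@pytest.fixture(scope="session")
def panel():
    return DEFAULT_PANEL


@pytest.fixture(scope="session")
def training_set():
    return simulate_training_set(TRAIN_N_PER_CLASS, TRAIN_DEPTH, TRAIN_SEED)


@pytest.fixture(scope="session")
def trained_model(training_set, panel):
    return train_classifier(training_set, panel)


@pytest.fixture()
def noiseless_marker():
    """Marker with no stutter and a point-mass 4-nt deletion."""
    return MarkerDef("toy", 24, 0.0, 4.0, 0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
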