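import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from numstroop import ModelParameters, TrainingSchedule, train_module
from numstroop.experiments import ParticipantStore


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def trained_weights(params):
    """One fully trained numerical comparison module (default parameters)."""
    return train_module(TrainingSchedule(params.n_train), params, seed=7)[
        params.n_train
    ]


@pytest.fixture(scope="session")
def small_store(params):
    """A small matched-participant store (both modules, two checkpoints)."""
    return ParticipantStore.train(
        params, n_participants=3, seed=11, checkpoints=(18_000, 20_000)
    )
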