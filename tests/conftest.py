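import numpy as np
import pytest

from stressrp.models import ModelSpec
from stressrp.synthetic import SimParams, alternating_schedule, simulate_cohort, simulate_recording


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Short, fast recordings for unit tests (same physiology as defaults)."""
    return SimParams(recording_duration=240.0, episode_length=60.0)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return simulate_cohort(3, small_params, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_params):
    schedule = alternating_schedule(small_params.recording_duration,
                                    small_params.episode_length)
    return simulate_recording(small_params, schedule, seed=5, recording_id="r0")


@pytest.fixture(scope="session")
def tiny_spec() -> ModelSpec:
    """A miniature architecture (same block structure) for fast model tests."""
    return ModelSpec(branch_channels=(2, 3, 4, 4, 6),
                     conv_layers_per_block=(2, 2, 3, 3, 3),
                     input_size=32, head_hidden_dim=8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
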