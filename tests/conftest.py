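import numpy as np
import pytest

from alffpipe import SimulationConfig, generate_group, generate_subject


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """A fast configuration for unit tests (not the study conditions)."""
    return SimulationConfig(n_subjects=3, n_sessions=2, n_timepoints=64, rng_seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_subject(small_config, subject_index=0, session_index=0)


@pytest.fixture(scope="session")
def small_group(small_config):
    return generate_group(small_config)


@pytest.fixture(scope="session")
def default_group():
    """The default study conditions: 20 subjects x 2 sessions, seed 0."""
    return generate_group(SimulationConfig())
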