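import numpy as np
import pytest

from eyesync import CouplingSpec, SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def small_config():
    """One-minute coupled cohort config used across unit tests."""
    return SyntheticConfig(
        n_subjects=1, n_videos=2, duration_s=60.0, seed=7,
        couplings=(CouplingSpec("pupil_right", "F3", "delta", 0.9),))


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config, 0, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
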