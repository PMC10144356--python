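import numpy as np
import pytest

from wireskill import build_phantom, expert_profile, novice_profile, simulate_trial


@pytest.fixture(scope="session")
def phantom():
    return build_phantom()


@pytest.fixture(scope="session")
def expert():
    return expert_profile()


@pytest.fixture(scope="session")
def novice():
    return novice_profile()


@pytest.fixture(scope="session")
def fast_expert():
    """Expert profile at triple speed: short trials for unit tests."""
    return expert_profile(advance_speed=150.0, speed_sd=15.0)


@pytest.fixture(scope="session")
def fast_novice():
    return novice_profile(advance_speed=120.0, speed_sd=50.0, pause_prob=0.04)


@pytest.fixture(scope="session")
def novice_trial(phantom, novice):
    return simulate_trial(phantom, novice, "left_common_carotid", seed=3)


@pytest.fixture(scope="session")
def expert_trial(phantom, expert):
    return simulate_trial(phantom, expert, "left_common_carotid", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
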