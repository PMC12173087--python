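import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    from crowdtrack.paradigm import ParadigmConfig
    return ParadigmConfig()


@pytest.fixture
def default_observer():
    from crowdtrack.observer import ObserverConfig
    return ObserverConfig()


@pytest.fixture
def separated_jump_config():
    """Jump schedule with >= 2.1 s between jumps, for recovery analyses."""
    from crowdtrack.paradigm import ParadigmConfig
    return ParadigmConfig(jump_distances_deg=(0.5, 1.5, 2.5, 3.5, 4.5))
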