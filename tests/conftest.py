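import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from memcrit.agents import AgentConfig, simulate_session
from memcrit.value_coding import code_trials

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fmri_session():
    """One scanner-design session (480 trials, median-tracking feedback)."""
    return simulate_session(AgentConfig(condition="fmri_liberal", design="fmri", seed=11))


@pytest.fixture(scope="session")
def coded_fmri_sessions():
    """Four coded scanner sessions for regressor-level tests."""
    return [
        code_trials(simulate_session(AgentConfig(condition="fmri_liberal", design="fmri", seed=s)))
        for s in (11, 12, 13, 14)
    ]


@pytest.fixture(scope="session")
def behav_session():
    """One behavioural-design session (288 trials, adaptive feedback)."""
    return simulate_session(AgentConfig(condition="new_low", design="behav", seed=21))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
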