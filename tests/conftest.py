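import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from immunopet.core import SubjectInfo
from immunopet.simulate import SimulationConfig, generate_input_function

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def subject() -> SubjectInfo:
    """Mean-sized study subject: 2.12 kg rabbit given 7.2 MBq."""
    return SubjectInfo("rabbit-01", "rabbit", "UUO",
                       body_weight_kg=2.12, injected_activity_MBq=7.2)


@pytest.fixture
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=20)


@pytest.fixture
def input_tac(sim_config):
    """Noise-free arterial input on the radiowater frame schedule."""
    return generate_input_function(sim_config)
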