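import numpy as np
import pytest

from pausekin.scenarios import SimScenario


@pytest.fixture
def equilibrium_scenario() -> SimScenario:
    """Pre-translocation fluctuations at the study's rates, no bleaching."""
    return SimScenario(
        name="eq",
        mode="equilibrium",
        rate_matrix={"NR->R": 0.6, "R->NR": 0.2},
        duration=60.0,
        n_traces=20,
        seed=123,
    )


@pytest.fixture
def clean_injection_scenario() -> SimScenario:
    """Fast-binding injection design without photobleaching."""
    return SimScenario(
        name="inj",
        mode="injection",
        binding_wait_median=3.8,
        translocation_median=1.5,
        rate_matrix={},
        duration=60.0,
        injection_time=10.0,
        n_traces=40,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
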