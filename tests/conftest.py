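import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sim_config():
    """A fast simulation: fewer cells, shorter session, same statistics."""
    from calsync import SimulationConfig

    return SimulationConfig(n_cells=40, duration_s=240.0, seed=7)


@pytest.fixture
def quiet_sim_config():
    """Noise- and event-free configuration (silent limit)."""
    from calsync import SimulationConfig

    return SimulationConfig(n_cells=10, duration_s=60.0, rate_h=0.0,
                            rate_l=0.0, noise_sd=0.0, drift_amplitude=0.0,
                            seed=0)
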