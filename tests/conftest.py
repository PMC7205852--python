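import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cranioflow import (
    ModelParameters,
    run_to_steady_state,
    synth_arterial_inflow,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mean_params() -> ModelParameters:
    return ModelParameters.preset("table2_mean")


@pytest.fixture(scope="session")
def h_params() -> ModelParameters:
    return ModelParameters.preset("table2_H")


@pytest.fixture(scope="session")
def notched_inflow():
    """Synthetic notched arterial inflow at 60 bpm, 650 ml/min."""
    return synth_arterial_inflow(
        heart_rate=60.0, mean_flow=650.0, pulsatility=1.0,
        notch_depth=0.3, notch_phase=0.45,
    )


@pytest.fixture(scope="session")
def steady_cycle(mean_params, notched_inflow):
    """Converged steady-state cycle at mean parameters (shared across tests)."""
    cycle, n = run_to_steady_state(mean_params, notched_inflow)
    return cycle, n


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
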