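import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from hemosig import (
    SimulationConfig,
    load_bundled_signature,
    simulate_counts,
)


@pytest.fixture(scope="session")
def bundled_signature():
    return load_bundled_signature()


@pytest.fixture(scope="session")
def simulated_cohort():
    """Default 50-sample cohort with contamination fractions on [0, 0.3]."""
    return simulate_counts(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def clean_cohort():
    """Same study conditions but every sample uncontaminated."""
    cfg = SimulationConfig(seed=1, contamination_fractions=np.zeros(50))
    return simulate_counts(cfg)
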