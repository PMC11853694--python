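import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gradientscope as gx

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> gx.SyntheticSpec:
    """Reduced cohort used across pipeline tests: 80 regions, 20+20 subjects."""
    return gx.SyntheticSpec(
        n_regions=80, n_timepoints=100, n_patients=20, n_controls=20,
        n_genes=120, n_signal_genes=12, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return gx.simulate_timeseries_cohort(small_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
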