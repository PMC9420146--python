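import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from instarfit import simulate_hcw, spec_from_table1

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1_spec():
    """The published-summary simulation preset (n = 401, three instars)."""
    return spec_from_table1(seed=1)


@pytest.fixture(scope="session")
def table1_sample(table1_spec):
    """One labelled synthetic sample drawn from the preset at seed 1."""
    return simulate_hcw(table1_spec)


@pytest.fixture()
def two_cluster_values():
    """Two well-separated tight clusters of 50 points each (100 and 500 μm)."""
    rng = np.random.default_rng(7)
    return np.sort(
        np.concatenate(
            [rng.normal(100.0, 1.0, 50), rng.normal(500.0, 1.0, 50)]
        )
    )
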