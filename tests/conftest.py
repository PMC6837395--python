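import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def reference_params():
    from randotkit.normative import REFERENCE_PARAMS

    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across pipeline-level tests."""
    from randotkit.synth import CohortConfig, generate_cohort

    config = CohortConfig(n_children=2000)
    records, truth = generate_cohort(config, seed=11)
    return config, records, truth
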