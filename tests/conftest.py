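import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def cngp_cohort():
    from pcdkit.prevalence import CNGP_COHORT

    return CNGP_COHORT


@pytest.fixture
def example_catalog():
    from pcdkit.variant_catalog import example_catalog

    return example_catalog()
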