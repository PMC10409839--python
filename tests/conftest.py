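import pytest
from hypothesis import settings

import cipredict as cp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coeffs():
    return cp.DEFAULT_COEFFICIENTS


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient default-calibration cohort shared across tests."""
    return cp.generate_cohort(cp.GeneratorConfig(n_patients=60, seed=42))
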