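import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_scenario():
    """Calibrated reference transport scenario (session-wide, deterministic)."""
    from voclift import calibrate_reference_scenario
    return calibrate_reference_scenario()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
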