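import pytest
from hypothesis import HealthCheck, settings

from fachkrec.dynamics import enumerate_attractors
from fachkrec.model import build_fa_chkrec

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fa():
    return build_fa_chkrec()


@pytest.fixture(scope="session")
def wt_attractors(fa):
    """Exhaustive wild-type enumeration over all 2^25 initial states."""
    return enumerate_attractors(fa)
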