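import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phototrace.core_io import Trace
from phototrace.synthetic import light_curve_protocol, wt_like

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth():
    return wt_like()


@pytest.fixture(scope="session")
def protocol():
    return light_curve_protocol()


@pytest.fixture
def flat_trace():
    """Constant fluorescence trace over [0, 100] s."""
    t = np.linspace(0.0, 100.0, 1001)
    return Trace(time=t, values=np.full_like(t, 1.5), channel="fluorescence")
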