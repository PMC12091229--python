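import logging

import pytest
from hypothesis import HealthCheck, settings

from tenomech import ProbeConfig, SLSMaterial

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# pure-ramp curves legitimately log "no hold plateau" warnings constantly
logging.getLogger("tenomech.curve_io").setLevel(logging.ERROR)


@pytest.fixture
def probe():
    """Default noiseless probe: R=37.5 um, k=0.5 N/m, 10 um/s, 1 kHz."""
    return ProbeConfig()


@pytest.fixture
def sls_day0():
    """SLS whose analytic 10 s rigid-hold relaxation is 35% (tau = 2 s)."""
    return SLSMaterial.from_relaxation(35.0, tau=2.0, E0=1300.0)
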