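import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import p2x3kin as pk

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wt():
    """Wild-type placeholder parameters with the published TNP-ATP rates."""
    return pk.RateParameters()


@pytest.fixture(scope="session")
def binding_only():
    """Gating and desensitization switched off: pure three-site binding."""
    return pk.RateParameters(
        beta2=0, alpha2=0, beta3=0, alpha3=0, d1=0, d2=0, d3=0, d4=0
    )


@pytest.fixture(scope="session")
def states():
    return pk.enumerate_states()


TNP_KD_NM = 0.056 / 15.8 * 1e3  # ≈3.544


@pytest.fixture(scope="session")
def tnp_kd_nm():
    return TNP_KD_NM
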