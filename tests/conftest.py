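import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table_fe_c():
    from coordff import LJPairParams

    return LJPairParams(-21.49, 1.79)


@pytest.fixture(scope="session")
def table_o_params():
    """Reference two-site O2 parameters (magnitudes)."""
    return dict(eps1=4.37, sig1=2.74, eps2=6.55, sig2=1.90)
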