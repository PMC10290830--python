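import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from marz import SiteAlignment, inr_like_ppm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_alignment():
    return SiteAlignment(["AAAAAA", "AAAAAA", "TATAAA", "TATAAA"], label="toy")


@pytest.fixture
def inr_ppm():
    return inr_like_ppm()
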