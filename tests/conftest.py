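import numpy as np
import pytest

from cartafm import HertzParams, Profile


@pytest.fixture
def hertz_params() -> HertzParams:
    """Cartilage/CSC38 probe constants."""
    return HertzParams(V=0.5, k=0.08, R=30.0)


@pytest.fixture
def ramp_profile() -> Profile:
    """Hand-enumerable profile [0,1,2,3,4] with unit spacing."""
    return Profile(np.array([0.0, 1.0, 2.0, 3.0, 4.0]), spacing=1.0)
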