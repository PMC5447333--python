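import numpy as np
import pytest

from cyltrack import CameraIntrinsics, MarkerSpec
from cyltrack.geometry import build_model_points


@pytest.fixture(scope="session")
def spec():
    return MarkerSpec()


@pytest.fixture(scope="session")
def camera():
    return CameraIntrinsics()


@pytest.fixture(scope="session")
def model(spec):
    return build_model_points(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
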