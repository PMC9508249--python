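import numpy as np
import pytest

from cortexbcm.bcm import BCMParams
from cortexbcm.device import DeviceParams, calibrate_defaults
from cortexbcm.stdp import TripletParams


@pytest.fixture(scope="session")
def device_params() -> DeviceParams:
    return calibrate_defaults()


@pytest.fixture(scope="session")
def triplet_params() -> TripletParams:
    return TripletParams()


@pytest.fixture(scope="session")
def bcm_params() -> BCMParams:
    return BCMParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
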