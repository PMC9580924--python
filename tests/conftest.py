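import numpy as np
import pytest

from synedgews import AcquisitionConfig, RunConfig


@pytest.fixture
def acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture
def run_cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
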