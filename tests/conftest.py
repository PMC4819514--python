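import numpy as np
import pytest

from tumorquant.acquisition import AcquisitionParams, AIFModel
from tumorquant import synthetic


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def aif(acq) -> AIFModel:
    """Population AIF with the bolus arriving as the post-contrast block starts."""
    return AIFModel(onset_time=acq.n_pre * acq.frame_interval)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noiseless DCE phantom shared by the closure tests."""
    spec = synthetic.PhantomSpec(grid_shape=(14, 14, 14), noise_sd=0.0, seed=7)
    return spec, synthetic.make_dce_phantom(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
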