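import numpy as np
import pytest

from plaquesim.params import ModelParams, default_params


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """The shipped calibrated default parameter set."""
    return default_params()


@pytest.fixture()
def small_params(params) -> ModelParams:
    """A reduced geometry for fast mechanical/field tests."""
    return params.replace(L=24.0, H=36.0, B=18.0, grid_spacing=6.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
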