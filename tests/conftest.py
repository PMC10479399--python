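import numpy as np
import pytest

from talin_clutch import (
    BellParams,
    ChainConfig,
    MechanicalParams,
)


@pytest.fixture(scope="session")
def mech():
    return MechanicalParams()


@pytest.fixture(scope="session")
def unbind_slip():
    return BellParams(k0=0.17, dx=0.51)


@pytest.fixture(scope="session")
def unfold_default():
    return BellParams(k0=1e-4, dx=4.0)


@pytest.fixture(scope="session")
def chain_12():
    return ChainConfig(n_total=12, n_unfoldable=12, theta0=45.0, v_retro=20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
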