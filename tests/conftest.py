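import numpy as np
import pytest

from neuralwave import (
    ContinuumParams,
    get_config,
    wave_params,
)


@pytest.fixture(scope="session")
def ref_low():
    return get_config("reference_low_damping")


@pytest.fixture(scope="session")
def ref_mod():
    return get_config("reference_moderate")


@pytest.fixture(scope="session")
def wave_low(ref_low):
    return wave_params(ref_low)


@pytest.fixture(scope="session")
def wave_mod(ref_mod):
    return wave_params(ref_mod)


@pytest.fixture(scope="session")
def regime1():
    return get_config("regime_1")


@pytest.fixture(scope="session")
def regime2():
    return get_config("regime_2")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def scaled_params(c: ContinuumParams, beta: float) -> ContinuumParams:
    """Scale the spread coefficients by beta (wavenumbers scale by 1/sqrt(beta))."""
    return c.replace(
        D_EE=c.D_EE * beta, D_EI=c.D_EI * beta, D_IE=c.D_IE * beta, D_II=c.D_II * beta
    )
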