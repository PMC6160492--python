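import numpy as np
import pytest

from lintflux import DensityProfile, default_params, fill_time, mean_velocity


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def u_bar(params):
    return mean_velocity(params).u_bar


@pytest.fixture(scope="session")
def t_fill(params, u_bar):
    return fill_time(params, u_bar)


@pytest.fixture(scope="session")
def constant_n0(params):
    return DensityProfile.constant(params.transport.n0_level, params.transport.L)


@pytest.fixture(scope="session")
def gaussian_n0(params):
    L = params.transport.L
    return DensityProfile.gaussian(total=10.0, center=L / 2, width=L / 10, L=L)


@pytest.fixture(scope="session")
def tabulated_n0(params):
    L = params.transport.L
    x = np.linspace(0.0, L, 41)
    n = 100.0 * (1.0 + np.sin(2 * np.pi * x / L) ** 2)
    return DensityProfile.tabulated(x, n, L)
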