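import numpy as np
import pytest

from diracsp import build_complex, dirac_system, ngf_network


@pytest.fixture
def single_edge():
    return build_complex([[1, 2]])


@pytest.fixture
def path3():
    return build_complex([[1, 2], [2, 3]])


@pytest.fixture
def triangle():
    return build_complex([[1, 2], [2, 3], [1, 3]])


@pytest.fixture(scope="session")
def ngf20_system():
    """Benchmark NGF(20) skeleton with cached operator algebra."""
    return dirac_system(ngf_network(20, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
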