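import numpy as np
import pytest

from teasl.hadamard import SubBolusSchedule, build_scheme
from teasl.kinetics import KineticParams
from teasl.cohort import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def schedule():
    return SubBolusSchedule()


@pytest.fixture(scope="session")
def scheme():
    return build_scheme(7)


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture()
def small_phantom():
    return make_phantom(PhantomSpec.small(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240703)
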