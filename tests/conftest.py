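import numpy as np
import pytest

from actispec.materials import CrossSectionLibrary
from actispec.montecarlo import TransportConfig
from actispec.nuclides import builtin_ac225_chain


@pytest.fixture(scope="session")
def chain():
    return builtin_ac225_chain()


@pytest.fixture(scope="session")
def xs_library():
    return CrossSectionLibrary()


@pytest.fixture(scope="session")
def transport_config(xs_library):
    return TransportConfig(library=xs_library)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
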