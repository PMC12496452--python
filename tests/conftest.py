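import numpy as np
import pytest
from hypothesis import settings

import irtfit as it

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid81():
    return it.make_grid(81, -4.0, 4.0)


@pytest.fixture(scope="session")
def k0_pool(grid81):
    """Small misfit pool built from the order-1 (k=0) enumeration only."""
    return it.build_lmpa_pool(grid81, threshold=0.05, ks=(0,))


@pytest.fixture(scope="session")
def toy_grid3():
    return it.QuadratureGrid(points=np.array([-1.0, 0.0, 1.0]),
                             weights=np.array([0.25, 0.5, 0.25]))
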