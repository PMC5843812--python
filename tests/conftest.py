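import numpy as np
import pytest

import vialdosim as vd


@pytest.fixture(scope="session")
def chain():
    return vd.load_chain()


@pytest.fixture(scope="session")
def geometry():
    return vd.VialGeometry()


@pytest.fixture(scope="session")
def range_models():
    return vd.default_range_models()


@pytest.fixture(scope="session")
def reference_svalues():
    return vd.load_reference_svalues()


@pytest.fixture(scope="session")
def computed_svalues(chain, geometry):
    """Monte Carlo S-value table at a moderate history count, shared
    across the suite to keep runtime down."""
    return vd.svalues(chain, geometry, n=200_000, seed=12345)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)
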