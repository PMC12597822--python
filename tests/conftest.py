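import numpy as np
import pytest

import mthotspot as mh


@pytest.fixture(scope="session")
def rcrs_ref():
    """Full-length reference: real rCRS gene map, seeded synthetic sequence."""
    return mh.load_reference(seed=11)


@pytest.fixture(scope="session")
def toy_ref():
    """2-kb synthetic circular genome with 4 genes (one overlapping pair)."""
    return mh.toy_reference(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
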