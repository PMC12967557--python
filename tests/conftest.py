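import numpy as np
import pytest

from semimix import background


@pytest.fixture(scope="session")
def uniform_bg():
    return background("uniform")


@pytest.fixture(scope="session")
def gaussian_bg():
    return background("gaussian")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
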