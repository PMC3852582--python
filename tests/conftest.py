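import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mitodetect import make_psf


@pytest.fixture(scope="session")
def default_psf():
    return make_psf(2.0, 0.5, 5)


@pytest.fixture(scope="session")
def small_psf():
    """Narrow kernel for fast small-image solver tests."""
    return make_psf(2.0, 0.5, 3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
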