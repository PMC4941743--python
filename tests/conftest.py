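import numpy as np
import pytest

from enamelfractal import RasterTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20160706)


@pytest.fixture
def random_blob(rng):
    """A sparse random binary image with a guaranteed foreground pixel."""
    img = (rng.random((64, 64)) < 0.08).astype(np.uint8)
    img[32, 32] = 1
    return RasterTrace(img, specimen_id="blob")
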