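import logging

import numpy as np
import pytest

from hemotex.imaging_io import IntensityImage


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # warnings from degenerate-case handling are expected in several tests
    logging.getLogger("hemotex").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_image(rng):
    return IntensityImage(rng.random((32, 32)), source_id="random32")
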