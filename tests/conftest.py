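import numpy as np
import pytest

from crcapture import load_fixture, to_capture_history


@pytest.fixture(scope="session")
def breast_cells():
    return load_fixture("breast")


@pytest.fixture(scope="session")
def colorectal_cells():
    return load_fixture("colorectal")


@pytest.fixture(scope="session")
def breast_history(breast_cells):
    return to_capture_history(breast_cells)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
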