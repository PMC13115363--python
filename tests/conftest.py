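import numpy as np
import pytest

from msdafuse import io_formats


@pytest.fixture(scope="session")
def deap_layout():
    return io_formats.load_layout(io_formats.default_layout_path())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
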