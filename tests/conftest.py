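import numpy as np
import pytest

from plumezoo import read_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return read_table1_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20190727)
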