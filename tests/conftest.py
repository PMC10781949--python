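import numpy as np
import pytest

from msgfield import MessageSpec, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def four_cell():
    return make_fixture("four_cell")


@pytest.fixture
def eight_cell():
    return make_fixture("eight_cell")


@pytest.fixture
def chemical_msg():
    """A generic diffusive message matching the fixture expression profiles."""
    return MessageSpec(id="m", modality="chemical", decay_rate=1.0, ligand="msg", receptor="msgR")
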