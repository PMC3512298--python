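import numpy as np
import pytest

from micromyo.cell_models import get_model
from micromyo.fixtures import fixture_geometries
from micromyo.microstructure import build_basic_unit


@pytest.fixture(scope="session")
def unit():
    return build_basic_unit()


@pytest.fixture(scope="session")
def geoms():
    return fixture_geometries()


@pytest.fixture(scope="session")
def bdk():
    return get_model("bdk")


@pytest.fixture(scope="session")
def twovar():
    return get_model("test")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
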