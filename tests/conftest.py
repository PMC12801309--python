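import warnings

import pytest

from cdnakit.cd_builder import CDBuildSpec, FunctionalizationSpec, functionalize, stack_layers
from cdnakit.na_synth import DuplexSpec, build_duplex, build_two_tetrad_mock

warnings.filterwarnings("ignore", message=".*missing ring atoms.*")


@pytest.fixture(scope="session")
def cd0():
    """Neutral five-layer CD (coronene/circumcoronene stack)."""
    return stack_layers(CDBuildSpec((2, 3, 3, 3, 2)))


@pytest.fixture(scope="session")
def cd_plus(cd0):
    """Positively charged CD: nine NH3+ edge groups."""
    return functionalize(cd0, FunctionalizationSpec("NH3+", count=9, seed=1))


@pytest.fixture(scope="session")
def cd_minus(cd0):
    """Negatively charged CD: eleven COO- edge groups."""
    return functionalize(cd0, FunctionalizationSpec("COO-", count=11, seed=2))


@pytest.fixture(scope="session")
def cd7_plus():
    """Large seven-layer CD with 26 NH3+ groups."""
    cd = stack_layers(CDBuildSpec((3, 4, 5, 5, 5, 4, 3)))
    return functionalize(cd, FunctionalizationSpec("NH3+", count=26, seed=3))


@pytest.fixture(scope="session")
def duplex20():
    """20-bp ideal B-DNA duplex."""
    return build_duplex(DuplexSpec("ACGTACGTACGTACGTACGT"))


@pytest.fixture(scope="session")
def duplex20_overhang():
    """20-bp duplex with one unpaired 3' overhang base."""
    return build_duplex(DuplexSpec("ACGTACGTACGTACGTACGT", overhang_3p="A"))


@pytest.fixture(scope="session")
def tetrad_mock():
    """Two stacked guanine quartets (annotation-complete mock)."""
    return build_two_tetrad_mock()
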