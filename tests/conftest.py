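import numpy as np
import pytest

from g4repeats import ScanParams, vimentin_sequence
from g4repeats.synthetic_data import table1_fixtures


@pytest.fixture(scope="session")
def table1() -> dict[str, str]:
    return table1_fixtures()


@pytest.fixture(scope="session")
def vimentin() -> str:
    return vimentin_sequence()


@pytest.fixture(scope="session")
def double_params() -> ScanParams:
    return ScanParams.double()


@pytest.fixture(scope="session")
def triple_params() -> ScanParams:
    return ScanParams.triple()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
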