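import numpy as np
import pytest
from hypothesis import settings

from rtcea import default_parameters, default_tables

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundle():
    return default_parameters()


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture(scope="session")
def life_table(tables):
    return tables[0]


@pytest.fixture(scope="session")
def bg(tables):
    return tables[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
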