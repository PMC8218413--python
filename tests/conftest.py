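import numpy as np
import pytest

from aaapsurvey import load_table1_fixture, load_table3_fixture
from aaapsurvey.synthetic_data import random_cds


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table3():
    return load_table3_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ancestor_cds(rng):
    """A 300-codon stop-free ancestor used across divergence tests."""
    return random_cds(300, rng)


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))
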