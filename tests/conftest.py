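import numpy as np
import pytest

from mermine.seqio import load_rule_table
from mermine.synth import load_synthetic_reference


@pytest.fixture(scope="session")
def merA_table():
    return load_rule_table("merA")


@pytest.fixture(scope="session")
def merB_table():
    return load_rule_table("merB")


@pytest.fixture(scope="session")
def merA_ref():
    return load_synthetic_reference("merA")


@pytest.fixture(scope="session")
def merB_ref():
    return load_synthetic_reference("merB")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
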