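import numpy as np
import pytest

from gabakin import load_fixture, load_scheme


@pytest.fixture(scope="session")
def two_state():
    return load_fixture("two_state")


@pytest.fixture(scope="session")
def spont_wt():
    return load_fixture("spont_wt")


@pytest.fixture(scope="session")
def glig_wt():
    return load_fixture("glig_wt")


@pytest.fixture(scope="session")
def glig_leu():
    return load_fixture("glig_leu")


@pytest.fixture(scope="session")
def glig_cys():
    return load_fixture("glig_cys")


@pytest.fixture(scope="session")
def two_open():
    """Two open states of distinct lifetime entered from one closed hub.

    Open mixture has exact components tau = 10 ms (1/100 s^-1) and
    100 ms (1/10 s^-1) with entry-rate fractions 2/3 and 1/3.
    """
    return load_scheme({
        "name": "two_open",
        "states": [
            {"name": "R", "class": "closed"},
            {"name": "O1", "class": "open", "conductance_weight": 1},
            {"name": "O2", "class": "open", "conductance_weight": 1},
        ],
        "transitions": [
            {"from": "R", "to": "O1", "rate_name": "b1", "base_value": 1.0},
            {"from": "O1", "to": "R", "rate_name": "a1", "base_value": 100.0},
            {"from": "R", "to": "O2", "rate_name": "b2", "base_value": 0.5},
            {"from": "O2", "to": "R", "rate_name": "a2", "base_value": 10.0},
        ],
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
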