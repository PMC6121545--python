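import pytest

from noisecea.cea import base_case
from noisecea.markov import arms_from_params
from noisecea.synthetic import generate_reference_inputs


@pytest.fixture(scope="session")
def truth():
    return generate_reference_inputs()


@pytest.fixture(scope="session")
def params(truth):
    return truth.params


@pytest.fixture(scope="session")
def life_table(truth):
    return truth.life_table


@pytest.fixture(scope="session")
def arms(params):
    """(limited, year_round) arm specs at base-case values."""
    return arms_from_params(params)


@pytest.fixture(scope="session")
def base_results(params, life_table):
    """Deterministic base case: (CEAResult, traces by arm label)."""
    return base_case(params, life_table)
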