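import numpy as np
import pytest

from watermodels import load_reference


@pytest.fixture(scope="session")
def gas_exp():
    return load_reference("gas_exp")


@pytest.fixture(scope="session")
def gas_qm():
    return load_reference("gas_qm")


@pytest.fixture(scope="session")
def liquid():
    return load_reference("liquid_mp2_4mm")


@pytest.fixture(scope="session")
def rigid4_gas_exp():
    """Tabulated 4-point gas-exp model with its LJ parameters."""
    return load_reference("table2/gas_exp/4")


@pytest.fixture(scope="session")
def polarizable_global():
    """Tabulated globally optimal 3-point polarizable model."""
    return load_reference("table3/alpha_and_mu")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
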