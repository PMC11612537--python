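import numpy as np
import pytest

from tritherm import (
    ModelParameters,
    effective_rates,
    scenario_parameterization,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def baseline_scenario():
    return scenario_parameterization(1)


@pytest.fixture(scope="session")
def all_on_scenario():
    return scenario_parameterization(10)


@pytest.fixture(scope="session")
def baseline_rates(params, baseline_scenario):
    """Effective rates of the temperature-independent scenario (any T)."""
    return effective_rates(20.0, params, baseline_scenario)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240120)
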