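import warnings

import numpy as np
import pytest

from chronicost.cost_model import baseline_per_capita
from chronicost.synthetic_data import (
    CostConfig,
    VARIANTS,
    default_base_population,
    generate_cost_table,
    generate_epi_inputs,
    generate_population,
)


@pytest.fixture(scope="session")
def base_pop():
    return default_base_population()


@pytest.fixture(scope="session")
def epi(base_pop):
    return generate_epi_inputs(population=base_pop)


@pytest.fixture(scope="session")
def pop(base_pop):
    return generate_population(VARIANTS["G2L2W2"], base_pop, seed=2010)


@pytest.fixture(scope="session")
def cost_table(epi, pop):
    return generate_cost_table(CostConfig(), epi, pop, seed=2010)


@pytest.fixture(scope="session")
def noiseless_cost_table(epi, pop):
    return generate_cost_table(CostConfig(noise_sd=0.0), epi, pop, seed=2010)


@pytest.fixture(scope="session")
def profile(cost_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return baseline_per_capita(cost_table)
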