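import numpy as np
import pytest

from asthma_adherence import default_life_table, default_parameters
from asthma_adherence.parameters import LifeTable


@pytest.fixture()
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def zero_mortality_life_table():
    ages = np.arange(0, 111)
    z = np.zeros_like(ages, dtype=float)
    return LifeTable(ages=ages, qx_female=z, qx_male=z.copy())


def constant_mortality_life_table(q_annual: float) -> LifeTable:
    ages = np.arange(0, 111)
    q = np.full(ages.shape, q_annual, dtype=float)
    return LifeTable(ages=ages, qx_female=q, qx_male=q.copy())


def toy_microsim_parameters():
    """Fixed small parameterization for the microsimulation oracle."""
    p = default_parameters(tagged=False)
    p.horizon_years = 5.0
    return p
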