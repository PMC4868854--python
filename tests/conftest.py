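from dataclasses import replace

import numpy as np
import pytest

from nobsim import (
    DriverRecord,
    EnvironmentState,
    SimulationConfig,
    default_type_set,
    read_driver_csv,
)
from nobsim.cli import EXAMPLE_DRIVERS
from nobsim.trait_catalog import FunctionalTypeSet, TraitProfile


@pytest.fixture(scope="session")
def typeset():
    return default_type_set()


@pytest.fixture(scope="session")
def example_drivers():
    return read_driver_csv(EXAMPLE_DRIVERS)


@pytest.fixture
def rich_env():
    """Substrate-replete environment where every type can grow."""
    return EnvironmentState(no2=1e-3, oc=5e-3, o2=5e-3)


def make_profile(
    name="test",
    mu_max=1e-5,
    k_m_no2=100.0,
    v_max_no2=2e9 * 1e-5,
    growth_yield=0.05,
    mortality=3e-7,
    k_m_o2=1e-3,
    **kwargs,
) -> TraitProfile:
    """Single chemolithotroph with uptake capacity ~100x growth demand."""
    defaults = dict(
        name=name,
        strategy="K_chemolithotroph",
        v_max_no2=v_max_no2,
        k_m_no2=k_m_no2,
        k_m_o2=k_m_o2,
        v_max_oc=0.0,
        k_m_oc=500.0,
        v_max_c=v_max_no2,
        k_m_c=5.0,
        mu_max=mu_max,
        growth_yield=growth_yield,
        mortality=mortality,
    )
    defaults.update(kwargs)
    return TraitProfile(**defaults)


@pytest.fixture
def single_type():
    return FunctionalTypeSet((make_profile(),))
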