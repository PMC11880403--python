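import numpy as np
import pandas as pd
import pytest

from lakenbudget import (
    NBudget,
    PopulationSpec,
    RemovalModelParams,
    ScenarioConfig,
    assemble_budgets,
    generate_lakes,
)


@pytest.fixture(scope="session")
def params():
    return RemovalModelParams()


@pytest.fixture(scope="session")
def scenario():
    return ScenarioConfig()


@pytest.fixture
def worked_budget():
    """The hand-checkable reference lake: loading 100 t yr⁻¹ (60 inflow +
    40 deposition), outflow 60 t, removal 40 t, storage 200 t,
    volume 10⁸ m³ → 2 mg N L⁻¹."""
    return NBudget(
        lake_id="worked",
        loading_inflow=60_000.0,
        loading_deposition=40_000.0,
        loading=100_000.0,
        removal_flux=40_000.0,
        outflow=60_000.0,
        storage=200_000.0,
        removal_ratio=0.4,
        a_coeff=0.4,
        water_volume=1e8,
    )


@pytest.fixture(scope="session")
def population(params):
    """A 600-lake synthetic population shared across the suite."""
    return generate_lakes(PopulationSpec(n_lakes=600, seed=42), params)


@pytest.fixture(scope="session")
def budgets(population, params):
    b, _ = assemble_budgets(population, params, 0.4)
    return b


def random_budget(rng) -> NBudget:
    """A random well-formed budget; clamp rule applied to outflow.

    Masses are whole kilograms (exactly representable), so additive
    identities of the annual update can be checked bit-for-bit.
    """
    loading = float(rng.integers(1_000, 1_000_000))
    removal = float(rng.integers(0, int(1.5 * loading) + 1))
    dep = float(rng.integers(0, int(0.5 * loading) + 1))
    wv = rng.uniform(1e6, 1e9)
    storage = float(rng.integers(int(wv * 0.2 / 1000), int(wv * 8.0 / 1000)))
    return NBudget(
        lake_id=f"R{rng.integers(1e9)}",
        loading_inflow=loading - dep,
        loading_deposition=dep,
        loading=loading,
        removal_flux=removal,
        outflow=max(loading - removal, 0.0),
        storage=storage,
        removal_ratio=removal / loading,
        a_coeff=0.4,
        water_volume=wv,
    )
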