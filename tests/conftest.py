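import numpy as np
import pytest

from simcost import (
    AGE_BANDS,
    CostParameters,
    EarningsSchedule,
    LifeTable,
    MedicalCostTable,
    PriceIndex,
    Sex,
    ValuationConfig,
    default_profile_mix,
    generate_parameter_bundle,
    small_preset,
)


def make_life_table(p_female, p_male=None):
    """LifeTable from raw survival arrays (male defaults to female's)."""
    pf = np.asarray(p_female, dtype=float)
    pm = pf if p_male is None else np.asarray(p_male, dtype=float)
    return LifeTable({Sex.FEMALE: pf, Sex.MALE: pm})


def flat_earnings(amount, household=0.0):
    return EarningsSchedule({(s, b): (amount, household) for s in Sex for b in AGE_BANDS})


def zero_medical():
    return MedicalCostTable(
        {("scene_home", "*", "*"): 0.0}, transport_cost=0.0, autopsy_cost=0.0,
        autopsy_fraction=0.0,
    )


@pytest.fixture(scope="session")
def scenario():
    return small_preset(seed=7)


@pytest.fixture(scope="session")
def params(scenario):
    return generate_parameter_bundle(scenario)


@pytest.fixture(scope="session")
def profile_mix():
    return default_profile_mix()


@pytest.fixture
def toy_params(params):
    """Small, fast parameter set with a 20-age life table."""
    rng = np.random.default_rng(42)
    p = rng.uniform(0.85, 0.999, size=21)
    p[-1] = 0.0
    lt = make_life_table(p, np.clip(p - 0.02, 0, 1) * (p > 0))
    return CostParameters(
        life_table=lt,
        earnings=flat_earnings(30_000.0, 5_000.0),
        medical=zero_medical(),
        valuation=ValuationConfig(),
        price_index=PriceIndex({2019: 1.0}),
    )
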