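import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from obesim import (
    MortalityTable,
    RiskFactorVector,
    synthetic_life_table,
    toy_registry,
)
from obesim.risk import zero_registry


@pytest.fixture(scope="session")
def life_table():
    return synthetic_life_table()


@pytest.fixture(scope="session")
def flat_table():
    """Constant qx = 0.01 for both sexes, ages 0-120."""
    return MortalityTable({(a, s): 0.01 for a in range(121) for s in ("F", "M")})


@pytest.fixture(scope="session")
def registry():
    return toy_registry()


@pytest.fixture(scope="session")
def zero_risk_registry():
    return zero_registry()


@pytest.fixture
def rf():
    """Reference-group-like risk-factor vector."""
    return RiskFactorVector(
        age=48.5,
        sex_share_women=0.646,
        bmi=22.5,
        height=168.0,
        sbp=128.2,
        total_chol=203.7,
        hdl_chol=61.0,
        hba1c_pct=7.5,
        t2d_duration=5.9,
        triglycerides=118.9,
        share_tg_ge_150=0.224,
        share_smokers=0.493,
        share_antihypertensive=0.147,
        share_lipid_lowering=0.083,
        menopause_age=51.0,
    )
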