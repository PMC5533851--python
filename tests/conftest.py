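import numpy as np
import pytest
from hypothesis import settings

from diabcea import (
    CostSchedule,
    GlucoseState,
    ModelParameters,
    MortalityTable,
    UtilityTable,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Default parameter set with the synthetic Swedish-like mortality table."""
    return ModelParameters.default()


@pytest.fixture(scope="session")
def flat_mortality() -> MortalityTable:
    """Constant 1% annual all-cause mortality, no T2D-specific deaths."""
    return MortalityTable(bands=((0.0, 120.0, 0.01, 0.0),))


@pytest.fixture(scope="session")
def zero_mortality() -> MortalityTable:
    return MortalityTable(bands=((0.0, 120.0, 0.0, 0.0),))


def make_unit_utilities() -> UtilityTable:
    """HUW 1 for every living state, both sexes, arms and anchors."""
    values = {}
    for sex in ("male", "female"):
        for age in (30, 50, 70):
            for arm in ("control", "intervention"):
                for s in GlucoseState:
                    if s is not GlucoseState.DEAD:
                        values[(sex, age, arm, s)] = 1.0
    return UtilityTable(values=values)


def make_zero_costs() -> CostSchedule:
    return CostSchedule(
        t2d_direct=0.0,
        indirect_share=0.0,
        prediabetes_share=0.0,
        intervention_first_year=0.0,
        intervention_followup=0.0,
    )
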