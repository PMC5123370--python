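import pytest

from smalltrial import AccrualPlan, ErrorSpec, SurvivalAssumption


@pytest.fixture
def euramos_assumption() -> SurvivalAssumption:
    """Good-responder osteosarcoma working design: 70% 3-year EFS, target HR 0.63."""
    return SurvivalAssumption(control_survival=0.70, reference_time=3.0, hazard_ratio=0.63)


@pytest.fixture
def revised_assumption() -> SurvivalAssumption:
    """Same survival assumption with the more realistic HR target of 0.7."""
    return SurvivalAssumption(control_survival=0.70, reference_time=3.0, hazard_ratio=0.70)


@pytest.fixture
def two_sided_errors() -> ErrorSpec:
    return ErrorSpec(alpha=0.05, sidedness="two", power=0.80)


@pytest.fixture
def euramos_plan() -> AccrualPlan:
    """3.5 years of accrual, answer after 5 years in total."""
    return AccrualPlan(accrual_duration=3.5, total_duration=5.0)
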