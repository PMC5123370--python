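"""Events <-> patients conversion under uniform accrual and exponential survival.

The number of patients a time-to-event design must recruit is the required
event count divided by the probability that a recruited patient has an event
by the analysis.  With patients entering uniformly over an accrual window of
length ``a`` and analysed at calendar time ``T`` (measured from the first
entry), a patient entering at ``u ~ Uniform(0, a)`` is followed for ``T - u``,
so under a constant hazard ``lam``::

    P(event) = 1 - (1 / (lam * a)) * (exp(-lam * (T - a)) - exp(-lam * T))

with the obvious limits at ``a = 0`` (everyone followed for ``T``) and
``lam = 0`` (no events).  Averaging this probability over the two arms at
their respective hazards, with allocation weights, gives the per-patient mean
event probability the recruitment target divides by.

This is the minimal accrual model consistent with a design stated as
"accrue for a years, answer after T years"; it carries no loss-to-follow-up
allowance (the field exists on the plan but is fixed at zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .design import DesignError, SurvivalAssumption

__all__ = [
    "AccrualPlan",
    "PatientsResult",
    "prob_event",
    "mean_event_probability",
    "patients_required",
    "solve_total_duration",
]

# Bisection settings for solving total duration (years).
_BISECT_TOL = 1e-6
_BISECT_SPAN = 100.0


@dataclass(frozen=True)
class AccrualPlan:
    """Accrual duration ``a``, total duration ``T`` and allocation ratio.

    Durations are in years; ``total_duration`` runs from the first patient's
    entry to the analysis.  Allocation ratio is experimental:control; only
    1:1 is exercised by the published worked examples.
    """

    accrual_duration: float
    total_duration: float
    allocation_ratio: float = 1.0
    loss_to_followup: float = 0.0  # reserved; the model assumes none

    def __post_init__(self) -> None:
        if self.accrual_duration < 0.0:
            raise DesignError(f"accrual duration must be >= 0, got {self.accrual_duration}")
        if self.total_duration < self.accrual_duration:
            raise DesignError(
                f"total duration ({self.total_duration}) must be >= accrual "
                f"duration ({self.accrual_duration})"
            )
        if self.allocation_ratio <= 0.0:
            raise DesignError(f"allocation ratio must be positive, got {self.allocation_ratio}")
        if self.loss_to_followup != 0.0:
            raise DesignError("loss to follow-up is not modelled; it must be 0")


@dataclass(frozen=True)
class PatientsResult:
    """Recruitment target for a given event requirement.

    ``patients_rounded`` is the ceiling of the raw value, bumped to an even
    total under 1:1 allocation so both arms get a whole number of patients.
    """

    patients_raw: float
    patients_rounded: int
    mean_event_probability: float
    per_arm_event_probability: tuple[float, float]  # (control, experimental)


def prob_event(hazard: float, plan: AccrualPlan) -> float:
    """Probability a uniformly accrued patient has an event by the analysis.

    Continuous in the accrual duration at 0 and monotone in hazard and total
    duration; always in [0, 1].
    """
    if hazard < 0.0:
        raise DesignError(f"hazard must be >= 0, got {hazard}")
    if hazard == 0.0:
        return 0.0
    a, total = plan.accrual_duration, plan.total_duration
    la = hazard * a
    # 1 - exp(-lam (T-a)) * (1 - exp(-lam a)) / (lam a), stable as a -> 0
    factor = 1.0 if la < 1e-12 else -math.expm1(-la) / la
    return 1.0 - math.exp(-hazard * (total - a)) * factor


def mean_event_probability(assumption: SurvivalAssumption, plan: AccrualPlan) -> float:
    """Allocation-weighted event probability across the two arms."""
    p_control = prob_event(assumption.control_hazard, plan)
    p_experimental = prob_event(assumption.experimental_hazard, plan)
    w = plan.allocation_ratio / (1.0 + plan.allocation_ratio)
    return (1.0 - w) * p_control + w * p_experimental


def patients_required(
    events: int, assumption: SurvivalAssumption, plan: AccrualPlan
) -> PatientsResult:
    """Recruitment target delivering ``events`` pooled events by the analysis."""
    if events < 1:
        raise DesignError(f"events must be >= 1, got {events}")
    p_control = prob_event(assumption.control_hazard, plan)
    p_experimental = prob_event(assumption.experimental_hazard, plan)
    mean_p = mean_event_probability(assumption, plan)
    if mean_p <= 0.0:
        raise DesignError("mean event probability is 0; no patient total can deliver events")
    raw = events / mean_p
    rounded = math.ceil(raw - 1e-12)
    if plan.allocation_ratio == 1.0 and rounded % 2 == 1:
        rounded += 1
    return PatientsResult(raw, rounded, mean_p, (p_control, p_experimental))


def solve_total_duration(
    events: int,
    patients: int,
    assumption: SurvivalAssumption,
    plan_template: AccrualPlan,
) -> float:
    """Smallest total duration at which ``patients`` yield ``events`` events.

    Monotone bisection on ``T >= accrual_duration`` to 1e-6 years.  Raises
    :class:`DesignError` when no duration can suffice (the required event
    probability reaches or exceeds 1, e.g. events > patients).
    """
    if events < 1:
        raise DesignError(f"events must be >= 1, got {events}")
    target = events / patients
    if target >= 1.0:
        raise DesignError(
            f"{events} events from {patients} patients needs event probability "
            f"{target:.3f} >= 1; infeasible at any follow-up"
        )

    a = plan_template.accrual_duration

    def mean_p(total: float) -> float:
        plan = AccrualPlan(a, total, plan_template.allocation_ratio)
        return mean_event_probability(assumption, plan)

    lo, hi = a, a + _BISECT_SPAN
    if mean_p(lo) >= target:
        return lo
    if mean_p(hi) < target:
        raise DesignError(
            f"event probability at {hi:.1f} years ({mean_p(hi):.4f}) still below "
            f"the required {target:.4f}; design infeasible"
        )
    while hi - lo > _BISECT_TOL:
        mid = 0.5 * (lo + hi)
        if mean_p(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi
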