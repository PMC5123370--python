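"""Core sample-size machinery for two-arm time-to-event superiority trials.

The number of primary-outcome events needed by a log-rank test is driven by
four quantities: the target hazard ratio (HR), the significance level and its
sidedness, and the power.  Two standard event formulas are provided:

* a Schoenfeld-type formula, ``d = 4 (z_a + z_b)^2 / (ln HR)^2``, and
* a Freedman-type formula, ``d = ((1 + HR) / (1 - HR))^2 (z_a + z_b)^2``,

where ``z_a`` is the standard-normal quantile at ``1 - alpha`` (one-sided) or
``1 - alpha/2`` (two-sided) and ``z_b`` the quantile at the power.  A third
"combined" engine averages the two raw counts and rounds up; this calibration
reproduces published working-design tables that do not state their formula
(see the package methods note).  Both forms assume 1:1 allocation.

Also housed here: translations between a hazard ratio and the absolute
difference in event-free survival it implies at a reference time, under
proportional hazards with exponential survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.special import ndtri

__all__ = [
    "DesignError",
    "ErrorSpec",
    "SurvivalAssumption",
    "EventsResult",
    "normal_quantile",
    "events_schoenfeld",
    "events_freedman",
    "events_combined",
    "required_events",
    "hazard_from_survival",
    "hr_to_absolute",
    "absolute_to_hr",
]

Sidedness = Literal["one", "two"]
Rounding = Literal["nearest", "ceiling"]

EVENT_FORMULAS = ("schoenfeld", "freedman", "combined")


class DesignError(ValueError):
    """A design specification is invalid or infeasible."""


def normal_quantile(p: float) -> float:
    """Standard-normal quantile (inverse CDF), accurate well beyond 1e-6.

    Raises
    ------
    DesignError
        If ``p`` is outside the open interval (0, 1).
    """
    if not 0.0 < p < 1.0:
        raise DesignError(f"probability must lie strictly in (0, 1), got {p}")
    return float(ndtri(p))


@dataclass(frozen=True)
class ErrorSpec:
    """Type-I error rate, its sidedness, and power for a single trial.

    ``alpha`` is declared on the scale of the test actually used: a one-sided
    5% design and a two-sided 10% design are the same test on the benefit
    side, but are declared differently.
    """

    alpha: float
    sidedness: Sidedness = "two"
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DesignError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise DesignError(f"power must lie in (0, 1), got {self.power}")
        if self.sidedness not in ("one", "two"):
            raise DesignError(f"sidedness must be 'one' or 'two', got {self.sidedness!r}")
        if self.z_alpha + self.z_power <= 0.0:
            raise DesignError(
                "degenerate error specification: the alpha and power quantiles "
                f"sum to {self.z_alpha + self.z_power:.4f} <= 0"
            )

    @property
    def alpha_per_tail(self) -> float:
        """Significance level on the benefit tail."""
        return self.alpha / 2.0 if self.sidedness == "two" else self.alpha

    @property
    def z_alpha(self) -> float:
        return normal_quantile(1.0 - self.alpha_per_tail)

    @property
    def z_power(self) -> float:
        return normal_quantile(self.power)


@dataclass(frozen=True)
class SurvivalAssumption:
    """Control-arm event-free survival at a reference time, plus the target HR.

    Survival is taken to be exponential in each arm, so the control hazard is
    ``-ln(control_survival) / reference_time`` and benefit is ``hazard_ratio
    < 1`` (experimental vs control).
    """

    control_survival: float
    reference_time: float
    hazard_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 < self.control_survival < 1.0:
            raise DesignError(
                f"control survival must lie in (0, 1), got {self.control_survival}"
            )
        if self.reference_time <= 0.0:
            raise DesignError(f"reference time must be positive, got {self.reference_time}")
        if self.hazard_ratio <= 0.0:
            raise DesignError(f"hazard ratio must be positive, got {self.hazard_ratio}")

    @property
    def control_hazard(self) -> float:
        return hazard_from_survival(self.control_survival, self.reference_time)

    @property
    def experimental_hazard(self) -> float:
        return self.control_hazard * self.hazard_ratio


@dataclass(frozen=True)
class EventsResult:
    """Required events, raw and rounded, with the formula and rounding used."""

    raw: float
    rounded: int
    formula: str
    rounding: Rounding

    def __post_init__(self) -> None:
        if self.rounded < 1:
            raise DesignError(f"rounded events must be >= 1, got {self.rounded}")


def _round_events(raw: float, rounding: Rounding) -> int:
    if rounding == "nearest":
        return int(round(raw))
    if rounding == "ceiling":
        return int(math.ceil(raw))
    raise DesignError(f"unknown rounding policy {rounding!r}")


def _check_effect(assumption: SurvivalAssumption) -> None:
    if assumption.hazard_ratio == 1.0:
        raise DesignError("hazard ratio 1 specifies no effect; required events are undefined")


def events_schoenfeld(
    assumption: SurvivalAssumption,
    errors: ErrorSpec,
    rounding: Rounding = "nearest",
) -> EventsResult:
    """Schoenfeld-type required events: ``4 (z_a + z_b)^2 / (ln HR)^2``."""
    _check_effect(assumption)
    z = errors.z_alpha + errors.z_power
    raw = 4.0 * z * z / math.log(assumption.hazard_ratio) ** 2
    return EventsResult(raw, _round_events(raw, rounding), "schoenfeld", rounding)


def events_freedman(
    assumption: SurvivalAssumption,
    errors: ErrorSpec,
    rounding: Rounding = "nearest",
) -> EventsResult:
    """Freedman-type required events: ``((1+HR)/(1-HR))^2 (z_a + z_b)^2``."""
    _check_effect(assumption)
    z = errors.z_alpha + errors.z_power
    hr = assumption.hazard_ratio
    raw = ((1.0 + hr) / (1.0 - hr)) ** 2 * z * z
    return EventsResult(raw, _round_events(raw, rounding), "freedman", rounding)


def events_combined(
    assumption: SurvivalAssumption,
    errors: ErrorSpec,
    rounding: Rounding = "ceiling",
) -> EventsResult:
    """Mean of the Schoenfeld- and Freedman-type raw counts, rounded up.

    This is the default engine for design-ledger rows; its ceiling-rounded
    output matches published redesign tables whose generating formula is
    unstated (a calibration, documented in the methods note).
    """
    raw_s = events_schoenfeld(assumption, errors).raw
    raw_f = events_freedman(assumption, errors).raw
    raw = 0.5 * (raw_s + raw_f)
    return EventsResult(raw, _round_events(raw, rounding), "combined", rounding)


_ENGINES = {
    "schoenfeld": events_schoenfeld,
    "freedman": events_freedman,
    "combined": events_combined,
}

_DEFAULT_ROUNDING = {"schoenfeld": "nearest", "freedman": "nearest", "combined": "ceiling"}


def required_events(
    assumption: SurvivalAssumption,
    errors: ErrorSpec,
    formula: str = "combined",
    rounding: Rounding | None = None,
) -> EventsResult:
    """Dispatch to one of the event formulas by name.

    ``rounding=None`` selects each formula's default policy (nearest for the
    single formulas, ceiling for the combined engine).
    """
    try:
        engine = _ENGINES[formula]
    except KeyError:
        raise DesignError(
            f"unknown events formula {formula!r}; choose from {EVENT_FORMULAS}"
        ) from None
    if rounding is None:
        rounding = _DEFAULT_ROUNDING[formula]
    return engine(assumption, errors, rounding=rounding)


def hazard_from_survival(survival: float, time: float) -> float:
    """Constant hazard implied by event-free survival ``survival`` at ``time``."""
    if not 0.0 < survival <= 1.0:
        raise DesignError(f"survival must lie in (0, 1], got {survival}")
    if time <= 0.0:
        raise DesignError(f"time must be positive, got {time}")
    return -math.log(survival) / time


def hr_to_absolute(assumption: SurvivalAssumption) -> tuple[float, float]:
    """Experimental-arm survival and absolute improvement implied by the HR.

    Under proportional hazards, experimental survival at the reference time is
    ``control_survival ** HR``; the improvement is experimental minus control
    (negative when the experimental arm is worse).
    """
    experimental = assumption.control_survival ** assumption.hazard_ratio
    return experimental, experimental - assumption.control_survival


def absolute_to_hr(control_survival: float, experimental_survival: float) -> float:
    """Hazard ratio implied by survival on both arms at a common time.

    Inverse of :func:`hr_to_absolute`: ``ln(experimental) / ln(control)``.
    """
    for name, s in (("control", control_survival), ("experimental", experimental_survival)):
        if not 0.0 < s < 1.0:
            raise DesignError(f"{name} survival must lie strictly in (0, 1), got {s}")
    return math.log(experimental_survival) / math.log(control_survival)
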