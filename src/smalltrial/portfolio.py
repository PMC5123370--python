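"""Societal-perspective error arithmetic across a portfolio of trials.

When a disease area can only support a handful of trials, power and type-I
error are usefully evaluated over the whole set of trials rather than per
trial: the chance that *at least one* of several independent trials detects a
real effect (joint power), the chance that at least one positive result is a
false positive (joint type-I error), and the expected number of false-positive
trials among those run.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

from .design import DesignError

__all__ = [
    "Portfolio",
    "joint_power",
    "joint_type1",
    "expected_false_positives",
]


def _check_probability(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise DesignError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class Portfolio:
    """A set of independent trials in one disease area.

    ``positive_fraction`` is the hypothesised fraction of trials that report a
    positive result; ``alpha`` the per-trial type-I error rate.
    """

    trial_count: int
    alpha: float
    per_trial_power: tuple[float, ...] = field(default=())
    positive_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.trial_count < 0:
            raise DesignError(f"trial count must be >= 0, got {self.trial_count}")
        _check_probability("alpha", self.alpha)
        _check_probability("positive fraction", self.positive_fraction)
        for p in self.per_trial_power:
            _check_probability("power", p)
        if self.per_trial_power and len(self.per_trial_power) != self.trial_count:
            raise DesignError(
                f"{len(self.per_trial_power)} powers supplied for "
                f"{self.trial_count} trials"
            )


def joint_power(powers: Sequence[float]) -> float:
    """Probability that at least one of several independent trials rejects.

    ``1 - prod(1 - p_i)``; with one trial this is just its power, and three
    trials at 50% already give 87.5%.
    """
    if len(powers) == 0:
        raise DesignError("joint power of an empty portfolio is undefined")
    result = 1.0
    for p in powers:
        _check_probability("power", p)
        result *= 1.0 - p
    return 1.0 - result


def joint_type1(alpha: float, positive_trials: int) -> float:
    """Chance that at least one of ``positive_trials`` positives is a false one.

    ``1 - (1 - alpha)^t`` for ``t`` published positive results each tested at
    level ``alpha``; 0 when no positives are claimed.
    """
    if not 0.0 < alpha < 1.0:
        raise DesignError(f"alpha must lie in (0, 1), got {alpha}")
    if positive_trials < 0:
        raise DesignError(f"positive trial count must be >= 0, got {positive_trials}")
    return 1.0 - (1.0 - alpha) ** positive_trials


def expected_false_positives(
    trial_count: int,
    positive_fraction: float,
    alpha: float,
    of_negatives: bool = False,
) -> tuple[float, int]:
    """Expected number of false-positive trials, raw and nearest-integer.

    The default multiplies the trial count by the hypothesised positive
    fraction and the per-trial alpha (``N * pi * alpha``).  Setting
    ``of_negatives=True`` instead applies alpha to the hypothesised *null*
    trials (``N * (1 - pi) * alpha``) — the expected count of true nulls that
    reject — which some readers may prefer; the default matches the published
    tabulations this package reproduces.
    """
    if trial_count < 0:
        raise DesignError(f"trial count must be >= 0, got {trial_count}")
    _check_probability("positive fraction", positive_fraction)
    _check_probability("alpha", alpha)
    fraction = (1.0 - positive_fraction) if of_negatives else positive_fraction
    raw = trial_count * fraction * alpha
    return raw, int(round(raw))
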