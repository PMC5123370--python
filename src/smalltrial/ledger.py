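"""An ordered, auditable ledger of alterations to a working trial design.

Redesigning a trial for a smaller population proceeds as a sequence of small,
individually justified changes: first make the trial bigger (collaboration,
eligibility, accrual and follow-up time), then revisit the standard design
knobs (research arm, outcome, target effect, power), and only then the less
conventional ones (sidedness, relaxed alpha, covariate adjustment,
re-randomisation, external information).  The ledger records that
deliberation: every entry — quantitative or purely qualitative — appends a
recomputed design with its event and recruitment requirements and the deltas
against a declared reference row, yielding a table a protocol committee can
audit line by line.

Step ordering within the three groups above is enforced; a deliberate
out-of-order change (e.g. revisiting follow-up after the target effect has
been altered) requires an explicit override flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .accrual import AccrualPlan, PatientsResult, patients_required
from .design import (
    DesignError,
    ErrorSpec,
    EventsResult,
    Rounding,
    SurvivalAssumption,
    required_events,
)

__all__ = [
    "TrialDesign",
    "LedgerEntry",
    "DesignLedger",
    "build_design",
    "covariate_adjustment_annotation",
    "render_ledger",
    "LEDGER_COLUMNS",
    "STEPS",
]

# Fig-ure-style grouping of the framework steps: broaden first, then standard
# design knobs, then the less conventional alterations.
STEP_GROUPS: dict[str, int] = {
    "extend_collaboration": 1,
    "broaden_eligibility": 1,
    "increase_accrual_or_followup": 1,
    "change_research_arm": 2,
    "change_outcome": 2,
    "set_target_effect": 2,
    "set_power": 2,
    "set_sidedness": 3,
    "set_alpha": 3,
    "covariate_adjustment": 3,
    "rerandomisation_note": 3,
    "external_information_note": 3,
}
STEPS = tuple(STEP_GROUPS)

# Parameters each quantitative step may change.  Steps not listed here are
# qualitative: they annotate the deliberation without touching the numbers.
_STEP_PARAMETERS: dict[str, frozenset[str]] = {
    "increase_accrual_or_followup": frozenset({"accrual_duration", "total_duration"}),
    "change_research_arm": frozenset({"hazard_ratio"}),
    "change_outcome": frozenset({"control_survival", "reference_time"}),
    "set_target_effect": frozenset({"hazard_ratio"}),
    "set_power": frozenset({"power"}),
    "set_sidedness": frozenset({"sidedness"}),
    "set_alpha": frozenset({"alpha", "sidedness"}),
}

_ERROR_FIELDS = ("alpha", "sidedness", "power")
_ASSUMPTION_FIELDS = ("control_survival", "reference_time", "hazard_ratio")
_PLAN_FIELDS = ("accrual_duration", "total_duration", "allocation_ratio")

LEDGER_COLUMNS = (
    "scenario",
    "patients",
    "delta_patients",
    "events",
    "delta_events",
    "accrual_years",
    "total_years",
)


@dataclass(frozen=True)
class TrialDesign:
    """One fully parameterised two-arm time-to-event design with requirements.

    ``events`` and ``patients`` are always computed from (errors, assumption,
    plan) by :func:`build_design`; the events formula used is recorded on the
    result so rows computed with different engines remain distinguishable.
    """

    errors: ErrorSpec
    assumption: SurvivalAssumption
    plan: AccrualPlan
    events: EventsResult
    patients: PatientsResult
    label: str = ""

    def parameter(self, name: str) -> Any:
        for obj, names in (
            (self.errors, _ERROR_FIELDS),
            (self.assumption, _ASSUMPTION_FIELDS),
            (self.plan, _PLAN_FIELDS),
        ):
            if name in names:
                return getattr(obj, name)
        raise DesignError(f"unknown design parameter {name!r}")


def build_design(
    errors: ErrorSpec,
    assumption: SurvivalAssumption,
    plan: AccrualPlan,
    label: str = "",
    formula: str = "combined",
    rounding: Rounding | None = None,
) -> TrialDesign:
    """Compute events and recruitment for a parameter set, as a TrialDesign."""
    events = required_events(assumption, errors, formula=formula, rounding=rounding)
    patients = patients_required(events.rounded, assumption, plan)
    return TrialDesign(errors, assumption, plan, events, patients, label)


@dataclass(frozen=True)
class LedgerEntry:
    """One recorded framework alteration.

    Qualitative steps carry an empty ``parameter_change`` and zero deltas;
    quantitative steps hold the recomputed design and its deltas against the
    ledger's reference row.  ``step`` is ``None`` only for the baseline row.
    """

    step: str | None
    design: TrialDesign
    parameter_change: dict[str, tuple[Any, Any]] = field(default_factory=dict)
    delta_events: int = 0
    delta_patients: int = 0
    annotation: str = ""
    formula: str = "combined"
    allow_out_of_order: bool = False

    @property
    def group(self) -> int | None:
        return None if self.step is None else STEP_GROUPS[self.step]


def covariate_adjustment_annotation(
    design: TrialDesign, reclaimed_power: float
) -> LedgerEntry:
    """Annotation-only entry asserting the true power after covariate adjustment.

    Planning to adjust the primary analysis for prognostic covariates reclaims
    power without resizing the trial, so the entry leaves events, patients and
    all deltas untouched and records the asserted true power in its
    annotation.  ``reclaimed_power`` below the nominal design power is
    rejected — adjustment cannot take power away from an honest design.
    """
    if reclaimed_power < design.errors.power:
        raise DesignError(
            f"reclaimed power {reclaimed_power} is below the nominal "
            f"{design.errors.power}; covariate adjustment cannot reduce power"
        )
    return LedgerEntry(
        step="covariate_adjustment",
        design=replace(design, label=design.label or "Covariate adjustment"),
        annotation=f"true power >= {100 * reclaimed_power:g} % with planned covariate adjustment",
        formula=design.events.formula,
    )


class DesignLedger:
    """Immutable sequence of designs: a baseline plus appended alterations.

    ``apply`` returns a new ledger with one appended entry and never mutates
    earlier rows, so replaying the same alteration sequence from the same
    baseline always reproduces the same table.  Deltas are integer
    differences of the rounded requirements against the reference row
    (default: the first post-baseline row, matching the convention of
    comparing against the first revised working design rather than the
    original one).
    """

    def __init__(self, baseline: TrialDesign, reference_index: int | None = None):
        self._entries: list[LedgerEntry] = [
            LedgerEntry(step=None, design=baseline, formula=baseline.events.formula)
        ]
        self._reference_index = reference_index

    @property
    def entries(self) -> tuple[LedgerEntry, ...]:
        return tuple(self._entries)

    @property
    def baseline(self) -> TrialDesign:
        return self._entries[0].design

    @property
    def current(self) -> TrialDesign:
        return self._entries[-1].design

    @property
    def reference_index(self) -> int:
        """Row whose requirements the deltas are taken against."""
        if self._reference_index is not None:
            return self._reference_index
        return 1 if len(self._entries) > 1 else 0

    def __len__(self) -> int:
        return len(self._entries)

    def _copy(self) -> "DesignLedger":
        out = DesignLedger.__new__(DesignLedger)
        out._entries = list(self._entries)
        out._reference_index = self._reference_index
        return out

    def _check_order(self, step: str, allow_out_of_order: bool) -> None:
        groups = [e.group for e in self._entries if e.group is not None]
        if groups and STEP_GROUPS[step] < max(groups) and not allow_out_of_order:
            raise DesignError(
                f"step {step!r} belongs to framework group {STEP_GROUPS[step]} but "
                f"group {max(groups)} has already been entered; pass "
                "allow_out_of_order=True to record a deliberate revisit"
            )

    def apply(
        self,
        step: str,
        changes: dict[str, Any] | None = None,
        label: str = "",
        annotation: str = "",
        formula: str = "combined",
        allow_out_of_order: bool = False,
    ) -> "DesignLedger":
        """Append one framework alteration; returns the extended ledger.

        ``changes`` maps parameter names to new values and must name only
        parameters the given step is allowed to change; qualitative steps
        take no changes and copy the current design forward with zero deltas.
        """
        if step not in STEP_GROUPS:
            raise DesignError(f"unknown framework step {step!r}; choose from {STEPS}")
        self._check_order(step, allow_out_of_order)
        changes = dict(changes or {})
        allowed = _STEP_PARAMETERS.get(step, frozenset())
        for name in changes:
            if name not in allowed:
                raise DesignError(
                    f"step {step!r} cannot change parameter {name!r}"
                    + (f"; it may change {sorted(allowed)}" if allowed else
                       " (qualitative step: no parameters)")
                )

        current = self.current
        if changes:
            parameter_change = {k: (current.parameter(k), v) for k, v in changes.items()}
            errors = replace(
                current.errors, **{k: v for k, v in changes.items() if k in _ERROR_FIELDS}
            )
            assumption = replace(
                current.assumption,
                **{k: v for k, v in changes.items() if k in _ASSUMPTION_FIELDS},
            )
            plan = replace(
                current.plan, **{k: v for k, v in changes.items() if k in _PLAN_FIELDS}
            )
            design = build_design(
                errors, assumption, plan, label=label or step, formula=formula
            )
        else:
            parameter_change = {}
            design = replace(current, label=label or step)

        out = self._copy()
        entry = LedgerEntry(
            step=step,
            design=design,
            parameter_change=parameter_change,
            annotation=annotation,
            formula=formula if changes else current.events.formula,
            allow_out_of_order=allow_out_of_order,
        )
        out._entries.append(out._with_deltas(entry, len(out._entries)))
        # reference row may only now exist; refresh deltas of earlier rows
        out._entries = [
            out._with_deltas(e, i) for i, e in enumerate(out._entries)
        ]
        return out

    def annotate_covariate_adjustment(self, reclaimed_power: float) -> "DesignLedger":
        self._check_order("covariate_adjustment", allow_out_of_order=False)
        entry = covariate_adjustment_annotation(self.current, reclaimed_power)
        out = self._copy()
        out._entries.append(entry)
        return out

    def _with_deltas(self, entry: LedgerEntry, index: int) -> LedgerEntry:
        ref = self._entries[min(self.reference_index, len(self._entries) - 1)].design
        if index == 0:
            return replace(entry, delta_events=0, delta_patients=0)
        return replace(
            entry,
            delta_events=entry.design.events.rounded - ref.events.rounded,
            delta_patients=entry.design.patients.patients_rounded
            - ref.patients.patients_rounded,
        )

    # -- reporting ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tabular report, one row per entry, in the fixed column order."""
        rows = []
        for e in self._entries:
            d = e.design
            rows.append(
                {
                    "scenario": d.label or ("baseline" if e.step is None else e.step),
                    "patients": d.patients.patients_rounded,
                    "delta_patients": e.delta_patients,
                    "events": d.events.rounded,
                    "delta_events": e.delta_events,
                    "accrual_years": d.plan.accrual_duration,
                    "total_years": d.plan.total_duration,
                }
            )
        frame = pd.DataFrame(rows, columns=list(LEDGER_COLUMNS))
        # the baseline row carries no deltas
        frame.loc[0, ["delta_patients", "delta_events"]] = pd.NA
        frame["delta_patients"] = frame["delta_patients"].astype("Int64")
        frame["delta_events"] = frame["delta_events"].astype("Int64")
        return frame

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        base = self.baseline
        alterations = []
        for e in self._entries[1:]:
            alterations.append(
                {
                    "step": e.step,
                    "label": e.design.label,
                    "changes": {k: to_ for k, (_, to_) in e.parameter_change.items()},
                    "annotation": e.annotation,
                    "formula": e.formula,
                    "allow_out_of_order": e.allow_out_of_order,
                }
            )
        return {
            "baseline": {
                "label": base.label,
                "alpha": base.errors.alpha,
                "sidedness": base.errors.sidedness,
                "power": base.errors.power,
                "control_survival": base.assumption.control_survival,
                "reference_time": base.assumption.reference_time,
                "hazard_ratio": base.assumption.hazard_ratio,
                "accrual_duration": base.plan.accrual_duration,
                "total_duration": base.plan.total_duration,
                "allocation_ratio": base.plan.allocation_ratio,
                "formula": base.events.formula,
                "rounding": base.events.rounding,
            },
            "reference_index": self._reference_index,
            "alterations": alterations,
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "DesignLedger":
        b = data["baseline"]
        baseline = build_design(
            ErrorSpec(b["alpha"], b["sidedness"], b["power"]),
            SurvivalAssumption(b["control_survival"], b["reference_time"], b["hazard_ratio"]),
            AccrualPlan(b["accrual_duration"], b["total_duration"], b.get("allocation_ratio", 1.0)),
            label=b.get("label", ""),
            formula=b.get("formula", "combined"),
            rounding=b.get("rounding"),
        )
        ledger = cls(baseline, reference_index=data.get("reference_index"))
        for alt in data.get("alterations", []):
            if alt["step"] == "covariate_adjustment" and "reclaimed_power" in alt:
                ledger = ledger.annotate_covariate_adjustment(alt["reclaimed_power"])
                continue
            ledger = ledger.apply(
                alt["step"],
                changes=alt.get("changes") or {},
                label=alt.get("label", ""),
                annotation=alt.get("annotation", ""),
                formula=alt.get("formula", "combined"),
                allow_out_of_order=alt.get("allow_out_of_order", False),
            )
        return ledger

    def save(self, path: str | Path) -> None:
        """Write the ledger recipe as JSON or YAML (by file extension)."""
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DesignLedger":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)


def render_ledger(ledger: DesignLedger) -> pd.DataFrame:
    """Design table for a ledger (scenario, patients, events, deltas, durations)."""
    if len(ledger) == 0:  # pragma: no cover - constructor guarantees a baseline
        raise DesignError("empty ledger")
    return ledger.to_frame()
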