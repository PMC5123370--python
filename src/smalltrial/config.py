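"""Structured design configuration files (YAML or JSON).

A configuration document describes one working trial design, optionally
followed by a list of ledger alterations, a portfolio block and a simulation
block.  Loading is strict: unknown keys are rejected, probabilities are
validated, and load -> save -> load is the identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .accrual import AccrualPlan
from .design import DesignError, ErrorSpec, SurvivalAssumption
from .ledger import DesignLedger, TrialDesign, build_design

__all__ = ["ConfigError", "DesignConfig", "load_config", "save_config"]

SCHEMA_VERSION = 1

_DESIGN_KEYS = {
    "label": str,
    "alpha": float,
    "sidedness": str,
    "power": float,
    "control_survival": float,
    "reference_time": float,
    "hazard_ratio": float,
    "accrual_duration": float,
    "total_duration": float,
    "allocation_ratio": float,
    "formula": str,
    "rounding": str,
}
_DESIGN_REQUIRED = {
    "alpha", "power", "control_survival", "reference_time",
    "hazard_ratio", "accrual_duration", "total_duration",
}
_ALTERATION_KEYS = {"step", "label", "changes", "annotation", "formula",
                    "allow_out_of_order", "reclaimed_power"}
_PORTFOLIO_KEYS = {"trial_count", "alpha", "per_trial_power", "positive_fraction",
                   "positive_trials"}
_SIMULATION_KEYS = {"true_hazard_ratio", "replications", "seed", "analysis_trigger",
                    "hazard_multipliers", "membership_probs", "stratified_analysis",
                    "patients"}
_TOP_KEYS = {"schema_version", "design", "alterations", "portfolio", "simulation"}


class ConfigError(DesignError):
    """A configuration document is malformed."""


def _reject_unknown(mapping: dict[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


@dataclass
class DesignConfig:
    """Parsed configuration: raw blocks plus the built design objects."""

    design_params: dict[str, Any]
    alterations: list[dict[str, Any]] = field(default_factory=list)
    portfolio: dict[str, Any] | None = None
    simulation: dict[str, Any] | None = None

    def build_design(self) -> TrialDesign:
        p = self.design_params
        return build_design(
            ErrorSpec(p["alpha"], p.get("sidedness", "two"), p["power"]),
            SurvivalAssumption(p["control_survival"], p["reference_time"], p["hazard_ratio"]),
            AccrualPlan(p["accrual_duration"], p["total_duration"], p.get("allocation_ratio", 1.0)),
            label=p.get("label", ""),
            formula=p.get("formula", "combined"),
            rounding=p.get("rounding"),
        )

    def build_ledger(self) -> DesignLedger:
        return DesignLedger.from_dict(
            {"baseline": self.design_params, "alterations": self.alterations}
        )

    def to_dict(self) -> dict[str, Any]:
        doc: dict[str, Any] = {"schema_version": SCHEMA_VERSION, "design": dict(self.design_params)}
        if self.alterations:
            doc["alterations"] = [dict(a) for a in self.alterations]
        if self.portfolio is not None:
            doc["portfolio"] = dict(self.portfolio)
        if self.simulation is not None:
            doc["simulation"] = dict(self.simulation)
        return doc


def _validate(doc: dict[str, Any]) -> DesignConfig:
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "configuration root")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}; expected {SCHEMA_VERSION}")
    if "design" not in doc:
        raise ConfigError("configuration must contain a 'design' block")

    design = doc["design"]
    _reject_unknown(design, set(_DESIGN_KEYS), "design block")
    missing = _DESIGN_REQUIRED - set(design)
    if missing:
        raise ConfigError(f"design block missing required key(s): {', '.join(sorted(missing))}")
    for key in ("alpha", "power", "control_survival"):
        value = design[key]
        if not isinstance(value, (int, float)) or not 0 < value < 1:
            raise ConfigError(f"design.{key} must be a probability in (0, 1), got {value!r}")

    alterations = doc.get("alterations", []) or []
    for i, alt in enumerate(alterations):
        _reject_unknown(alt, _ALTERATION_KEYS, f"alterations[{i}]")
        if "step" not in alt:
            raise ConfigError(f"alterations[{i}] missing 'step'")

    portfolio = doc.get("portfolio")
    if portfolio is not None:
        _reject_unknown(portfolio, _PORTFOLIO_KEYS, "portfolio block")
    simulation = doc.get("simulation")
    if simulation is not None:
        _reject_unknown(simulation, _SIMULATION_KEYS, "simulation block")

    return DesignConfig(
        design_params=dict(design),
        alterations=[dict(a) for a in alterations],
        portfolio=dict(portfolio) if portfolio is not None else None,
        simulation=dict(simulation) if simulation is not None else None,
    )


def load_config(path: str | Path) -> DesignConfig:
    """Load and validate a YAML or JSON design configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    elif path.suffix == ".json":
        doc = json.loads(text)
    else:
        raise ConfigError(f"unrecognised configuration extension {path.suffix!r}; use .yaml/.yml/.json")
    return _validate(doc)


def save_config(config: DesignConfig, path: str | Path) -> None:
    """Write a configuration back out (format chosen by extension)."""
    path = Path(path)
    doc = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        raise ConfigError(f"unrecognised configuration extension {path.suffix!r}; use .yaml/.yml/.json")
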