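"""Sensitivity sweeps: how requirements move with alpha and sidedness."""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import replace

import pandas as pd

from .accrual import patients_required
from .design import required_events
from .ledger import TrialDesign

__all__ = ["sweep_alpha", "plot_sweep"]


def sweep_alpha(
    design: TrialDesign,
    alphas: Sequence[float],
    sidedness_set: Iterable[str] = ("one", "two"),
    formula: str = "combined",
) -> pd.DataFrame:
    """Requirements over a grid of significance levels and sidedness choices.

    One row per (alpha, sidedness) pair with the events and patients the
    design would need, all other parameters held at the given design's
    values.  Within each sidedness, requirements fall as alpha grows; a
    one-sided level equals a two-sided level of twice the size.
    """
    rows = []
    for sidedness in sidedness_set:
        for alpha in alphas:
            errors = replace(design.errors, alpha=alpha, sidedness=sidedness)
            events = required_events(design.assumption, errors, formula=formula)
            patients = patients_required(events.rounded, design.assumption, design.plan)
            rows.append(
                {
                    "alpha": alpha,
                    "sidedness": sidedness,
                    "events": events.rounded,
                    "events_raw": events.raw,
                    "patients": patients.patients_rounded,
                }
            )
    return pd.DataFrame(rows, columns=["alpha", "sidedness", "events", "events_raw", "patients"])


def plot_sweep(grid: pd.DataFrame, path: str) -> None:
    """Write a simple patients-vs-alpha chart, one line per sidedness."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for sidedness, sub in grid.groupby("sidedness"):
        sub = sub.sort_values("alpha")
        ax.plot(sub["alpha"], sub["patients"], marker="o", label=f"{sidedness}-sided")
    ax.set_xlabel("significance level")
    ax.set_ylabel("patients required")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
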