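"""Normalize TCR-hybridoma activation readouts against control conditions.

Two pure normalizations are exposed: net stimulation (background
subtraction, floored at zero) and stimulation relative to a positive
control (background-corrected ratio).  Replicates are aggregated as
mean +/- SEM, by default before normalization of the means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateControlError(ValueError):
    """Positive control does not exceed background."""


def _check_percent(value: float, name: str) -> None:
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} must be a percent in [0,100], got {value!r}")


def net_stimulation(sample: float, background: float) -> float:
    """Background-subtracted percent positive, floored at 0."""
    _check_percent(sample, "sample")
    _check_percent(background, "background")
    return max(sample - background, 0.0)


def relative_stimulation(sample: float, background: float, positive: float) -> float:
    """Percent of the positive control, after background correction.

    ``100 * (sample - background) / (positive - background)``, floored at
    0; values above 100 are possible for supra-control stimulation.
    """
    _check_percent(sample, "sample")
    _check_percent(background, "background")
    _check_percent(positive, "positive")
    if positive <= background:
        raise DegenerateControlError(
            f"positive control ({positive}) must exceed background ({background})"
        )
    return max(100.0 * (sample - background) / (positive - background), 0.0)


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    mean: float
    sem: float
    n: int


def aggregate_replicates(readings: pd.DataFrame, value: str = "pct_positive") -> pd.DataFrame:
    """Mean +/- SEM of *value* per condition.

    *readings* needs ``condition`` and *value* columns (``replicate`` is
    informational).  SEM is 0 for single replicates.
    """
    grouped = readings.groupby("condition", sort=False)[value]
    out = grouped.agg(mean="mean", n="count")
    out["sem"] = grouped.sem(ddof=1).fillna(0.0)
    return out.reset_index()[["condition", "mean", "sem", "n"]]


def normalize_table(
    readings: pd.DataFrame,
    background: str,
    positive: str,
    value: str = "pct_positive",
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Net and relative stimulation per condition against two named controls.

    By default, replicate means are formed first and then normalized; with
    ``per_replicate`` each replicate is normalized against the control
    means before aggregation.
    """
    summary = aggregate_replicates(readings, value=value)
    by_cond = summary.set_index("condition")
    for ctrl in (background, positive):
        if ctrl not in by_cond.index:
            raise ValueError(f"control condition {ctrl!r} not in readings")
    bg = float(by_cond.loc[background, "mean"])
    pos = float(by_cond.loc[positive, "mean"])

    if per_replicate:
        rows = []
        for cond, sub in readings.groupby("condition", sort=False):
            nets = [net_stimulation(v, bg) for v in sub[value]]
            rels = [relative_stimulation(v, bg, pos) for v in sub[value]]
            rows.append(
                {
                    "condition": cond,
                    "mean": float(np.mean(sub[value])),
                    "sem": float(sub[value].sem(ddof=1)) if len(sub) > 1 else 0.0,
                    "n": len(sub),
                    "net": float(np.mean(nets)),
                    "relative": float(np.mean(rels)),
                }
            )
        return pd.DataFrame(rows)

    summary["net"] = [net_stimulation(v, bg) for v in summary["mean"]]
    summary["relative"] = [
        relative_stimulation(v, bg, pos) for v in summary["mean"]
    ]
    return summary
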