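"""Cumulative plantar tissue stress (CPTS) models.

CPTS is the daily mechanical dose at the ulcer site, combining how hard each
step loads the site (PTI, kPa.s), how many loading cycles occur (strides/day)
and, in model 2, a shear weighting (thermal stress response, dimensionless):

    model 1:  CPTS_day = sum_c  PTI_c * strides_c          / 1000   [MPa.s]
    model 2:  CPTS_day = sum_c  PTI_c * strides_c * TSR_c  / 1000   [MPa.s]

with c ranging over the two conditions (in-device, non-device).  The division
by 1000 converts kPa.s to MPa.s.  A participant's summary is the arithmetic
mean of the per-day values over *valid* monitoring days, in MPa.s/day.

Model 2 requires TSR for both conditions; where thermal imaging was not
collected, model 1 is still computed and model 2 reported unavailable.
Negative TSR makes negative day values possible; they are kept (the weighting
is applied as defined) and flagged.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingFactorError, NonAdherentError
from .types import Condition

__all__ = ["CptsInputs", "CptsResult", "cpts_day_model1", "cpts_day_model2",
           "cpts_summary", "compute_cpts"]

_KPA_S_TO_MPA_S = 1e-3


@dataclass
class CptsInputs:
    """Per-participant factors feeding the CPTS models.

    pti_by_condition : dict Condition -> kPa.s (mean over the trial protocol)
    tsr_by_condition : dict Condition -> dimensionless, or None if thermal
        imaging was unavailable.
    daily_counts : DataFrame indexed by date with integer columns
        ``in_device`` and ``non_device`` (stride counts), plus boolean
        ``valid`` (valid monitoring day).
    """

    pti_by_condition: dict
    daily_counts: pd.DataFrame
    tsr_by_condition: dict | None = None

    def __post_init__(self):
        for col in ("in_device", "non_device", "valid"):
            if col not in self.daily_counts.columns:
                raise MissingFactorError(f"daily_counts missing column {col!r}")

    @property
    def has_tsr(self) -> bool:
        return (self.tsr_by_condition is not None
                and Condition.IN_DEVICE in self.tsr_by_condition
                and Condition.NON_DEVICE in self.tsr_by_condition)


@dataclass
class CptsResult:
    """Per-day and summary CPTS with provenance of each factor."""

    per_day: pd.DataFrame  # index date; columns model1, [model2], valid
    summary_model1: float  # MPa.s/day
    summary_model2: float | None
    n_valid_days: int
    negative_model2_days: int = 0
    factor_provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model1_mpa_s_per_day": self.summary_model1,
            "model2_mpa_s_per_day": self.summary_model2,
            "n_valid_days": self.n_valid_days,
            "negative_model2_days": self.negative_model2_days,
            "per_day": {
                str(d): row.dropna().to_dict()
                for d, row in self.per_day.iterrows()
            },
            "factor_provenance": self.factor_provenance,
        }


def _get_pti(inputs: CptsInputs, cond: Condition, strides: float) -> float:
    pti = inputs.pti_by_condition.get(cond)
    if pti is None:
        if strides > 0:
            raise MissingFactorError(
                f"PTI missing for condition {cond.value} with {strides:g} strides"
            )
        return 0.0
    return float(pti)


def cpts_day_model1(inputs: CptsInputs, day) -> float:
    """Model-1 CPTS for one day, in MPa.s."""
    row = inputs.daily_counts.loc[day]
    s_in, s_non = float(row["in_device"]), float(row["non_device"])
    pti_in = _get_pti(inputs, Condition.IN_DEVICE, s_in)
    pti_non = _get_pti(inputs, Condition.NON_DEVICE, s_non)
    return (pti_in * s_in + pti_non * s_non) * _KPA_S_TO_MPA_S


def cpts_day_model2(inputs: CptsInputs, day) -> float:
    """Model-2 (shear-weighted) CPTS for one day, in MPa.s."""
    if not inputs.has_tsr:
        raise MissingFactorError("model 2 requires TSR for both conditions")
    row = inputs.daily_counts.loc[day]
    s_in, s_non = float(row["in_device"]), float(row["non_device"])
    pti_in = _get_pti(inputs, Condition.IN_DEVICE, s_in)
    pti_non = _get_pti(inputs, Condition.NON_DEVICE, s_non)
    tsr_in = float(inputs.tsr_by_condition[Condition.IN_DEVICE])
    tsr_non = float(inputs.tsr_by_condition[Condition.NON_DEVICE])
    return (pti_in * s_in * tsr_in + pti_non * s_non * tsr_non) * _KPA_S_TO_MPA_S


def cpts_summary(per_day: pd.DataFrame, valid: pd.Series | None = None) -> CptsResult:
    """Average per-day CPTS over valid days for each available model."""
    if valid is None:
        valid = per_day["valid"]
    valid = valid.astype(bool)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise NonAdherentError(0, 1)
    m1 = float(per_day.loc[valid, "model1"].mean())
    m2 = None
    neg = 0
    if "model2" in per_day.columns and per_day["model2"].notna().all():
        vals = per_day.loc[valid, "model2"]
        m2 = float(vals.mean())
        neg = int((vals < 0).sum())
    out = per_day.copy()
    out["valid"] = valid
    return CptsResult(per_day=out, summary_model1=m1, summary_model2=m2,
                      n_valid_days=n_valid, negative_model2_days=neg)


def compute_cpts(inputs: CptsInputs) -> CptsResult:
    """Evaluate both models on every day and summarise over valid days."""
    days = inputs.daily_counts.index
    per_day = pd.DataFrame(index=days)
    per_day["model1"] = [cpts_day_model1(inputs, d) for d in days]
    if inputs.has_tsr:
        per_day["model2"] = [cpts_day_model2(inputs, d) for d in days]
    res = cpts_summary(per_day, inputs.daily_counts["valid"])
    res.factor_provenance = {
        "pti": {c.value: inputs.pti_by_condition.get(c)
                for c in Condition},
        "tsr": (None if inputs.tsr_by_condition is None else
                {c.value: inputs.tsr_by_condition.get(c) for c in Condition}),
    }
    return res
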