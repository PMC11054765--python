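"""Stance-phase detection and ulcer-site PPP/PTI from pressure frame series.

Two measurement protocols are supported:

- ``walking``: one in-shoe (insole dialect) trial at self-selected speed;
  stance phases are segmented from total force, gait initiation/termination
  steps trimmed, and at least 12 midgait steps are required for validity.
- ``two_step``: barefoot platform measurements by the 2-step protocol, one
  foot contact per trial, four trials averaged.

The regional pressure curve at the ulcer site is, per frame, the maximum over
the masked sensors (cluster-peak reduction as used by in-shoe analysis
software; an area-weighted mean is available via ``reduction="mean"``).
PPP is the maximum of that curve over the stance, PTI its trapezoidal time
integral.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, InvalidTrialError, ProtocolError
from .types import Condition, PressureFrameSeries

__all__ = [
    "RegionMask", "StancePhase", "TrialPressureSummary",
    "detect_stance_phases", "select_midgait_steps", "step_metrics",
    "trial_summary", "default_force_threshold_n",
]

# 5% of body weight; default body mass 70 kg
DEFAULT_BODY_MASS_KG = 70.0
GRAVITY = 9.81


def default_force_threshold_n(body_mass_kg: float = DEFAULT_BODY_MASS_KG,
                              fraction: float = 0.05) -> float:
    return body_mass_kg * GRAVITY * fraction


@dataclass
class RegionMask:
    """Ulcer-site sensor selection.

    Insole dialect: explicit sensor ids.  Platform dialect: grid cells whose
    centre lies within ``radius_mm`` of the ulcer coordinate ``center_mm``.
    """

    label: str = "ulcer_site"
    sensor_ids: list[str] | None = None
    center_mm: tuple[float, float] | None = None
    radius_mm: float = 10.0

    def resolve(self, series: PressureFrameSeries) -> np.ndarray:
        """Indices of the masked sensors within the series geometry."""
        if self.sensor_ids is not None:
            lookup = {sid: i for i, sid in enumerate(series.sensor_ids)}
            missing = [s for s in self.sensor_ids if s not in lookup]
            if missing:
                raise InputError(f"mask sensors not in geometry: {missing}")
            idx = np.array([lookup[s] for s in self.sensor_ids], dtype=int)
        elif self.center_mm is not None:
            d = np.linalg.norm(series.geometry - np.asarray(self.center_mm), axis=1)
            idx = np.nonzero(d <= self.radius_mm)[0]
        else:
            raise InputError("mask needs sensor_ids or center_mm")
        if idx.size == 0:
            raise InputError("mask selects no sensors")
        return idx

    def to_dict(self) -> dict:
        d = {"label": self.label}
        if self.sensor_ids is not None:
            d["sensors"] = list(self.sensor_ids)
        else:
            d["center_mm"] = list(self.center_mm)
            d["radius_mm"] = self.radius_mm
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegionMask":
        if "sensors" in d:
            return cls(label=d.get("label", "ulcer_site"), sensor_ids=d["sensors"])
        return cls(label=d.get("label", "ulcer_site"),
                   center_mm=tuple(d["center_mm"]),
                   radius_mm=float(d.get("radius_mm", 10.0)))


@dataclass
class StancePhase:
    """Half-open frame-index interval [start, end) of one foot contact."""

    start: int
    end: int
    duration_s: float

    def __post_init__(self):
        if self.end <= self.start or self.duration_s <= 0:
            raise InputError("stance phase must have positive duration")


@dataclass
class TrialPressureSummary:
    ppp: float                 # kPa
    pti: float                 # kPa.s
    n_steps_used: int
    condition: Condition | None
    protocol: str              # "walking" | "two_step"
    meta: dict = field(default_factory=dict)


def detect_stance_phases(series: PressureFrameSeries,
                         force_threshold_n: float | None = None,
                         min_duration_s: float = 0.1,
                         floor_fraction: float = 0.05) -> list[StancePhase]:
    """Contiguous runs of frames whose total force stays above threshold.

    Total force is sum(pressure * sensor area) per frame.  Runs shorter than
    ``min_duration_s`` are discarded as contact artefacts.  Each detected run
    is then expanded outward while the force stays above a noise floor
    (``floor_fraction`` of the threshold), so the phase spans the whole
    loading curve from foot contact to lift-off rather than only the frames
    above the detection threshold; expansion never merges adjacent phases.
    Set ``floor_fraction=None`` to disable the expansion.
    """
    if series.times.size == 0:
        raise InputError("empty pressure series")
    if force_threshold_n is None:
        force_threshold_n = default_force_threshold_n()
    if force_threshold_n <= 0:
        raise InputError("force threshold must be positive")
    force = series.total_force_newton()
    loaded = force >= force_threshold_n
    runs = []
    padded = np.concatenate([[False], loaded, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for s, e in zip(edges[::2], edges[1::2]):
        if (e - s) / series.sampling_rate >= min_duration_s:
            runs.append([int(s), int(e)])
    if floor_fraction is not None:
        floor = floor_fraction * force_threshold_n
        n = force.size
        for i, run in enumerate(runs):
            lo_bound = runs[i - 1][1] if i > 0 else 0
            hi_bound = runs[i + 1][0] if i + 1 < len(runs) else n
            while run[0] > lo_bound and force[run[0] - 1] > floor:
                run[0] -= 1
            while run[1] < hi_bound and force[run[1]] > floor:
                run[1] += 1
    return [StancePhase(start=s, end=e, duration_s=(e - s) / series.sampling_rate)
            for s, e in runs]


def select_midgait_steps(phases: list[StancePhase], trim: int = 2,
                         min_steps: int = 12) -> list[StancePhase]:
    """Drop `trim` initiation and `trim` termination steps; enforce validity.

    Raises :class:`InvalidTrialError` when fewer than ``min_steps`` midgait
    steps remain, which marks the whole walking trial invalid.
    """
    if trim < 0:
        raise InputError("trim must be >= 0")
    kept = phases[trim:len(phases) - trim] if trim else list(phases)
    if len(kept) < min_steps:
        raise InvalidTrialError(n_steps=len(kept), min_steps=min_steps)
    return kept


def _regional_curve(series: PressureFrameSeries, mask_idx: np.ndarray,
                    reduction: str) -> np.ndarray:
    sub = series.frames[:, mask_idx]
    if reduction == "max":
        return sub.max(axis=1)
    if reduction == "mean":
        area = np.broadcast_to(
            np.asarray(series.sensor_area_cm2, dtype=float), (series.n_sensors,)
        )[mask_idx]
        return (sub * area).sum(axis=1) / area.sum()
    raise InputError(f"unknown reduction {reduction!r}")


def step_metrics(series: PressureFrameSeries, phase: StancePhase,
                 mask: RegionMask, reduction: str = "max") -> tuple[float, float]:
    """(PPP kPa, PTI kPa.s) of one stance at the masked region.

    PTI integrates the regional curve over the half-open phase with the
    trapezoidal rule at the series' own sampling instants.
    """
    if phase.end > series.frames.shape[0]:
        raise InputError("stance phase outside the series")
    idx = mask.resolve(series)
    m = _regional_curve(series, idx, reduction)[phase.start:phase.end]
    t = series.times[phase.start:phase.end]
    ppp = float(m.max())
    pti = float(np.trapezoid(m, t))
    return ppp, pti


def trial_summary(series, mask: RegionMask, protocol: str = "walking",
                  condition: Condition | None = None,
                  force_threshold_n: float | None = None,
                  min_duration_s: float = 0.1,
                  trim: int = 2, min_steps: int = 12,
                  reduction: str = "max",
                  step_aggregate: str = "mean") -> TrialPressureSummary:
    """Protocol-level PPP/PTI summary at the ulcer site.

    ``walking``: one insole series; PPP/PTI are aggregated (mean by default,
    max via ``step_aggregate="max"``) over the midgait steps of a valid trial.
    ``two_step``: exactly four single-contact platform series; each trial's
    single contact is measured and the four trials averaged.
    """
    agg = {"mean": np.mean, "max": np.max}.get(step_aggregate)
    if agg is None:
        raise InputError(f"unknown step aggregate {step_aggregate!r}")
    if protocol == "walking":
        if isinstance(series, (list, tuple)):
            if len(series) != 1:
                raise ProtocolError("walking protocol takes exactly one series")
            series = series[0]
        phases = detect_stance_phases(series, force_threshold_n, min_duration_s)
        steps = select_midgait_steps(phases, trim=trim, min_steps=min_steps)
        metrics = [step_metrics(series, ph, mask, reduction) for ph in steps]
        ppps, ptis = zip(*metrics)
        return TrialPressureSummary(
            ppp=float(agg(ppps)), pti=float(agg(ptis)),
            n_steps_used=len(steps), condition=condition, protocol=protocol,
            meta={"trim": trim, "min_steps": min_steps, "reduction": reduction,
                  "step_aggregate": step_aggregate},
        )
    if protocol == "two_step":
        if not isinstance(series, (list, tuple)) or len(series) != 4:
            raise ProtocolError("two-step protocol requires exactly 4 trials")
        ppps, ptis = [], []
        for s in series:
            phases = detect_stance_phases(s, force_threshold_n, min_duration_s)
            if len(phases) != 1:
                raise ProtocolError(
                    f"two-step trial must contain exactly 1 contact, found {len(phases)}"
                )
            ppp, pti = step_metrics(s, phases[0], mask, reduction)
            ppps.append(ppp)
            ptis.append(pti)
        return TrialPressureSummary(
            ppp=float(np.mean(ppps)), pti=float(np.mean(ptis)),
            n_steps_used=4, condition=condition, protocol=protocol,
            meta={"reduction": reduction},
        )
    raise ProtocolError(f"unknown protocol {protocol!r}")
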