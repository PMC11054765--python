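"""End-to-end per-participant and cohort CPTS drivers.

``run_participant`` executes pressure -> activity -> adherence -> (thermal)
-> CPTS on one participant's stream files.  A missing or failing factor never
aborts the run: it downgrades to a structured per-factor completion status
drawn from the feasibility taxonomy (complete / non_adherent / technical /
combination / refusal / dropout), mirroring how feasibility is accounted in
clinical practice.  ``run_cohort`` aggregates participants, compares healed
vs non-healed groups on CPTS and every underlying factor, and tallies
feasibility per stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .activity import daily_activity
from .adherence import (adherence_percent, classify_strides,
                        wear_intervals_from_temperature)
from .errors import (ConfigurationError, CptsError, InputError,
                     NonAdherentError)
from .model import CptsInputs, CptsResult, compute_cpts
from .pressure import RegionMask, trial_summary
from .stats import (FeasibilityRecord, GroupComparison, compare_groups,
                    feasibility_tally)
from .synth import (INSOLE_ULCER_SENSOR_IDS, PLATFORM_ULCER_CENTER_MM,
                    GroundTruthManifest)
from .thermal import thermal_stress_response
from .types import Condition

__all__ = ["StudyConfig", "ParticipantBundle", "ParticipantResult",
           "CohortReport", "run_participant", "run_cohort",
           "bundles_from_cohort_dir"]

STAGES = ("baseline", "week4", "week8")


@dataclass
class StudyConfig:
    """All algorithm parameters for one study run.

    ``style`` selects the non-device pressure dialect: "au" uses regular-
    footwear insole walking trials, "nl" barefoot platform 2-step trials
    (and never requires CPTS model 2, since thermal imaging was unavailable
    in that style).
    """

    style: str = "au"                      # "au" | "nl"
    stage: str = "baseline"
    # pressure
    force_threshold_n: float = 34.3        # 5% of 70 kg body weight
    min_stance_s: float = 0.1
    trim_steps: int = 2
    min_midgait_steps: int = 12
    reduction: str = "max"
    step_aggregate: str = "mean"
    insole_mask_sensors: list = field(
        default_factory=lambda: list(INSOLE_ULCER_SENSOR_IDS))
    platform_mask_center_mm: tuple = PLATFORM_ULCER_CENTER_MM
    platform_mask_radius_mm: float = 10.0
    # activity
    min_wear_h: float = 12.0
    min_valid_days: int = 4
    # adherence / wear
    wear_on_threshold_c: float = 27.0
    wear_off_threshold_c: float = 25.0
    wear_min_slope_c: float = 0.5
    wear_max_gap_h: float = 2.0

    def __post_init__(self):
        if self.style not in ("au", "nl"):
            raise ConfigurationError(f"unknown study style {self.style!r}")
        if self.stage not in STAGES:
            raise ConfigurationError(f"stage must be one of {STAGES}")

    def insole_mask(self) -> RegionMask:
        return RegionMask(sensor_ids=list(self.insole_mask_sensors))

    def platform_mask(self) -> RegionMask:
        return RegionMask(center_mm=tuple(self.platform_mask_center_mm),
                          radius_mm=self.platform_mask_radius_mm)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ParticipantBundle:
    """Stream file paths and outcome labels for one participant."""

    id: str
    pressure_in_device: Path | None = None
    pressure_non_device: list | None = None  # 1 walking file or 4 platform files
    strides: Path | None = None              # stride-event CSV
    acceleration: Path | None = None         # raw accel CSV (alternative)
    temperature: Path | None = None
    thermal: Path | None = None
    healed: bool | None = None
    area_reduction_75pct: bool | None = None
    refused: bool = False
    dropout: bool = False
    style: str | None = None  # per-participant override of StudyConfig.style


FACTORS = ("pressure_in_device", "pressure_non_device", "activity",
           "adherence", "thermal", "cpts")


@dataclass
class ParticipantResult:
    id: str
    statuses: dict                       # factor -> taxonomy status
    cpts: CptsResult | None = None
    factors: dict = field(default_factory=dict)  # numeric factor estimates
    healed: bool | None = None
    notes: list = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return self.statuses.get("cpts") == "complete"

    def overall_status(self) -> str:
        """Participant-level feasibility status for the stage."""
        if self.complete:
            return "complete"
        bad = {f: s for f, s in self.statuses.items()
               if f != "cpts" and s != "complete"}
        kinds = set(bad.values())
        if kinds == {"refusal"}:
            return "refusal"
        if kinds == {"dropout"}:
            return "dropout"
        if "non_adherent" in kinds and ("technical" in kinds):
            return "combination"
        if "non_adherent" in kinds:
            return "non_adherent"
        return "technical"


def _pressure_factor(bundle, config, cond: Condition, style: str):
    """Trial summary for one condition, or (None, status)."""
    if cond is Condition.IN_DEVICE:
        paths = [bundle.pressure_in_device] if bundle.pressure_in_device else None
        protocol, mask = "walking", config.insole_mask()
    else:
        paths = bundle.pressure_non_device
        if paths is not None and not isinstance(paths, (list, tuple)):
            paths = [paths]
        if style == "nl":
            protocol, mask = "two_step", config.platform_mask()
        else:
            protocol, mask = "walking", config.insole_mask()
    if not paths:
        return None, "technical"
    try:
        series = [cio.read_stream(p, "pressure") for p in paths]
        summary = trial_summary(
            series if protocol == "two_step" else series[0],
            mask, protocol=protocol, condition=cond,
            force_threshold_n=config.force_threshold_n,
            min_duration_s=config.min_stance_s, trim=config.trim_steps,
            min_steps=config.min_midgait_steps, reduction=config.reduction,
            step_aggregate=config.step_aggregate)
        return summary, "complete"
    except CptsError:
        return None, "technical"


def run_participant(bundle: ParticipantBundle, config: StudyConfig,
                    ) -> ParticipantResult:
    """Execute the full CPTS chain for one participant.

    Every failure mode maps onto the feasibility taxonomy; only an unreadable
    configuration raises.
    """
    style = bundle.style or config.style
    statuses = {}
    factors = {}
    notes = []
    if bundle.refused or bundle.dropout:
        status = "refusal" if bundle.refused else "dropout"
        return ParticipantResult(id=bundle.id, healed=bundle.healed,
                                 statuses={f: status for f in FACTORS})

    # --- plantar pressure, both conditions
    pti = {}
    for cond, key in ((Condition.IN_DEVICE, "pressure_in_device"),
                      (Condition.NON_DEVICE, "pressure_non_device")):
        summary, status = _pressure_factor(bundle, config, cond, style)
        statuses[key] = status
        if summary is not None:
            pti[cond] = summary.pti
            factors[f"pti_{cond.value}"] = summary.pti
            factors[f"ppp_{cond.value}"] = summary.ppp

    # --- weight-bearing activity
    strides = None
    daily = None
    try:
        if bundle.strides is not None:
            strides = cio.read_stream(bundle.strides, "strides")
            wear_monitor = None
        elif bundle.acceleration is not None:
            from .activity import detect_monitor_wear, detect_strides
            accel = cio.read_stream(bundle.acceleration, "acceleration")
            strides = detect_strides(accel)
            wear_monitor = detect_monitor_wear(accel)
        else:
            raise InputError("no activity source")
        daily, mean_strides = daily_activity(
            strides, wear_monitor, min_wear_h=config.min_wear_h,
            min_valid_days=config.min_valid_days)
        factors["mean_daily_strides"] = mean_strides
        statuses["activity"] = "complete"
    except NonAdherentError as exc:
        statuses["activity"] = "non_adherent"
        notes.append(str(exc))
    except CptsError as exc:
        statuses["activity"] = "technical"
        notes.append(str(exc))

    # --- adherence (device wear x strides)
    counts = None
    try:
        if bundle.temperature is None:
            raise InputError("no temperature log")
        if strides is None or daily is None:
            raise InputError("adherence needs valid activity data")
        log = cio.read_stream(bundle.temperature, "temperature")
        wear = wear_intervals_from_temperature(
            log, on_threshold=config.wear_on_threshold_c,
            off_threshold=config.wear_off_threshold_c,
            min_slope=config.wear_min_slope_c,
            max_gap_h=config.wear_max_gap_h)
        counts = classify_strides(strides, wear)
        valid_days = daily.index[daily["valid"]]
        summary = adherence_percent(counts, valid_days)
        factors["adherence_percent"] = summary.adherence_percent
        statuses["adherence"] = "complete"
    except NonAdherentError:
        statuses["adherence"] = "non_adherent"
    except CptsError as exc:
        if statuses.get("activity") == "non_adherent":
            statuses["adherence"] = "non_adherent"
        else:
            statuses["adherence"] = "technical"
        notes.append(str(exc))

    # --- thermal stress response (model 2 weighting)
    tsr = None
    if style == "nl":
        statuses["thermal"] = "complete"  # not part of the NL protocol
    else:
        try:
            if bundle.thermal is None:
                raise InputError("no thermal readings")
            pairs = cio.read_stream(bundle.thermal, "thermal")
            tsr = {p.condition: thermal_stress_response(p).value for p in pairs}
            if set(tsr) != {Condition.IN_DEVICE, Condition.NON_DEVICE}:
                raise InputError("thermal readings missing a condition")
            factors["tsr_in_device"] = tsr[Condition.IN_DEVICE]
            factors["tsr_non_device"] = tsr[Condition.NON_DEVICE]
            statuses["thermal"] = "complete"
        except CptsError as exc:
            statuses["thermal"] = "technical"
            tsr = None
            notes.append(str(exc))

    # --- CPTS fusion
    cpts = None
    needed = ["pressure_in_device", "pressure_non_device", "activity",
              "adherence"]
    if all(statuses.get(k) == "complete" for k in needed):
        try:
            day_counts = counts.copy()
            day_counts["valid"] = daily["valid"].reindex(
                day_counts.index).fillna(False)
            inputs = CptsInputs(pti_by_condition=pti, daily_counts=day_counts,
                                tsr_by_condition=tsr)
            cpts = compute_cpts(inputs)
            factors["cpts_model1"] = cpts.summary_model1
            if cpts.summary_model2 is not None:
                factors["cpts_model2"] = cpts.summary_model2
            statuses["cpts"] = "complete"
        except CptsError as exc:
            statuses["cpts"] = "technical"
            notes.append(str(exc))
    else:
        bad = {k: statuses.get(k) for k in needed
               if statuses.get(k) != "complete"}
        kinds = set(bad.values())
        if "non_adherent" in kinds and "technical" in kinds:
            statuses["cpts"] = "combination"
        elif "non_adherent" in kinds:
            statuses["cpts"] = "non_adherent"
        else:
            statuses["cpts"] = "technical"
    return ParticipantResult(id=bundle.id, statuses=statuses, cpts=cpts,
                             factors=factors, healed=bundle.healed, notes=notes)


COMPARE_VARIABLES = (
    "cpts_model1", "cpts_model2", "pti_in_device", "ppp_in_device",
    "pti_non_device", "ppp_non_device", "mean_daily_strides",
    "adherence_percent", "tsr_in_device", "tsr_non_device",
)


@dataclass
class CohortReport:
    results: list
    factor_table: pd.DataFrame           # participant x factor estimates
    comparisons: list                    # GroupComparison rows
    completion_matrix: pd.DataFrame      # participant x stage x factor statuses
    feasibility: pd.DataFrame
    notices: list = field(default_factory=list)

    def comparison_table(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_row() for c in self.comparisons])

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.factor_table.to_csv(out / "factors.csv")
        self.comparison_table().to_csv(out / "comparisons.csv", index=False)
        self.completion_matrix.to_csv(out / "completion_matrix.csv", index=False)
        self.feasibility.to_csv(out / "feasibility.csv", index=False)
        for res in self.results:
            if res.cpts is not None:
                cio.write_json(res.cpts.to_dict(), out / f"cpts_{res.id}.json")


def run_cohort(bundles: list, config: StudyConfig) -> CohortReport:
    """Per-participant results plus healed-vs-non-healed comparisons.

    Comparisons use Mann-Whitney U with effect size r on every CPTS factor;
    groups with fewer than one participant per side are skipped with a
    notice.  The completion matrix rows use only the feasibility taxonomy.
    """
    if len(bundles) < 2:
        raise InputError("cohort needs at least 2 participants")
    results = [run_participant(b, config) for b in bundles]
    factor_table = pd.DataFrame(
        [{**{"id": r.id, "healed": r.healed}, **r.factors} for r in results]
    ).set_index("id")

    comparisons, notices = [], []
    healed_mask = factor_table["healed"] == True  # noqa: E712 (NaN-safe)
    nonhealed_mask = factor_table["healed"] == False  # noqa: E712
    for var in COMPARE_VARIABLES:
        if var not in factor_table.columns:
            continue
        a = factor_table.loc[healed_mask, var].dropna()
        b = factor_table.loc[nonhealed_mask, var].dropna()
        if len(a) < 1 or len(b) < 1:
            notices.append(f"{var}: comparison skipped "
                           f"(healed n={len(a)}, non-healed n={len(b)})")
            continue
        comparisons.append(compare_groups(var, a, b))

    records = [FeasibilityRecord(r.id, config.stage, r.overall_status())
               for r in results]
    feas = feasibility_tally(records)
    matrix = pd.DataFrame([
        {"participant": r.id, "stage": config.stage, "factor": f,
         "status": r.statuses.get(f, "technical")}
        for r in results for f in FACTORS
    ])
    return CohortReport(results=results, factor_table=factor_table,
                        comparisons=comparisons, completion_matrix=matrix,
                        feasibility=feas, notices=notices)


def bundles_from_cohort_dir(cohort_dir) -> tuple[list, GroundTruthManifest]:
    """Build bundles from a directory written by ``generate_cohort``."""
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / "manifest.json"
    if not manifest_path.exists():
        raise InputError(f"no manifest.json in {cohort_dir}")
    import json
    manifest = GroundTruthManifest.from_json_dict(
        json.loads(manifest_path.read_text()))
    bundles = []
    for profile in manifest.profiles:
        pdir = cohort_dir / profile.id
        if profile.study_style == "nl":
            non = sorted(pdir.glob("pressure_non_device_trial*.csv"))
        else:
            p = pdir / "pressure_non_device.csv"
            non = [p] if p.exists() else []
        thermal = pdir / "thermal.json"
        bundles.append(ParticipantBundle(
            id=profile.id,
            pressure_in_device=(pdir / "pressure_in_device.csv"
                                if (pdir / "pressure_in_device.csv").exists()
                                else None),
            pressure_non_device=non or None,
            strides=(pdir / "strides.csv"
                     if (pdir / "strides.csv").exists() else None),
            temperature=(pdir / "temperature.csv"
                         if (pdir / "temperature.csv").exists() else None),
            thermal=thermal if thermal.exists() else None,
            healed=profile.healed,
            style=profile.study_style,
        ))
    return bundles, manifest
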