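"""Synthetic multi-sensor cohort generator with known ground truth.

Raw participant data for CPTS studies are not publicly deposited, so every
downstream stage of this package is validated against synthetic participants
whose true parameters are known exactly.  The generator emulates the four
streams of a two-cohort offloading study:

1. plantar pressure trials (insole walking dialect at 50 Hz with 99 sensors;
   barefoot platform dialect at 100 Hz, 4 sensors/cm^2, 2-step protocol);
2. weight-bearing activity (stride events in bouts; optionally rendered as
   raw 100 Hz trunk accelerometry over short windows);
3. in-device temperature logs every 15 min (first-order relaxation between
   ambient and skin set-points across don/doff events);
4. pre/post-walk thermal ROI pairs constructed to hit a target thermal
   stress response exactly in noise-free mode.

Default parameter ranges are the cohort IQRs of the published study
(:func:`cpts.datasets.factor_reference_ranges`): "AU-style" participants
include thermal imaging, "NL-style" participants do not and use barefoot
platform trials for the non-device condition.

Every stance pulse is a half-sine, p(t) = P sin(pi t / T), whose
pressure-time integral has the closed form 2 P T / pi -- the analytic oracle
used throughout the test-suite.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .datasets import factor_reference_ranges
from .errors import ConfigurationError, InfeasibilityError, InputError
from .types import (AccelerationSeries, Condition, PressureFrameSeries,
                    StrideEventSeries, TemperatureLog, ThermalReadingPair)

__all__ = [
    "ParticipantProfile", "GenerationConfig", "GroundTruthManifest",
    "generate_profile", "simulate_temperature_log", "simulate_stride_stream",
    "simulate_acceleration", "simulate_pressure_trial", "simulate_thermal_pair",
    "generate_cohort", "insole_geometry", "platform_geometry",
    "INSOLE_ULCER_SENSOR_IDS", "PLATFORM_ULCER_CENTER_MM", "halfsine_pti",
]

SKIN_SETPOINT_C = 32.0
AMBIENT_C = 21.0
TAU_MIN = 30.0
DEVICE_CLIP_G = 6.0


def halfsine_pti(peak_kpa: float, duration_s: float) -> float:
    """Closed-form PTI of a half-sine stance pulse: 2 P T / pi (kPa.s)."""
    return 2.0 * peak_kpa * duration_s / np.pi


# ------------------------------------------------------------------ profile

@dataclass
class ParticipantProfile:
    """Ground-truth parameters of one synthetic participant.

    ``wear_schedule`` is a list of daily (on_hour, off_hour) clock intervals,
    applied every monitoring day; intervals must be disjoint and ordered.
    PTI in kPa.s, PPP in kPa, TSR dimensionless (None when thermal imaging
    is not part of the study style).
    """

    id: str
    true_adherence: float
    true_daily_strides: int
    pti_in_device: float
    pti_non_device: float
    ppp_in_device: float
    ppp_non_device: float
    wear_schedule: list
    tsr_in_device: float | None = None
    tsr_non_device: float | None = None
    monitoring_days: int = 7
    healed: bool | None = None
    study_style: str = "au"
    start_date: str = "2024-03-04"  # a Monday

    def __post_init__(self):
        if not 0.0 <= self.true_adherence <= 1.0:
            raise ConfigurationError("adherence must be in [0, 1]")
        if self.true_daily_strides <= 0:
            raise ConfigurationError("daily strides must be positive")
        for v in (self.pti_in_device, self.pti_non_device,
                  self.ppp_in_device, self.ppp_non_device):
            if v <= 0:
                raise ConfigurationError("PTI and PPP must be strictly positive")
        if self.monitoring_days < 6:
            raise ConfigurationError("monitoring requires at least 6 days")
        sched = [(float(a), float(b)) for a, b in self.wear_schedule]
        for on, off in sched:
            if not (0.0 <= on < off <= 24.0):
                raise ConfigurationError("wear interval must satisfy 0<=on<off<=24")
        for (_, off0), (on1, _) in zip(sched, sched[1:]):
            if on1 < off0:
                raise ConfigurationError("wear intervals must be disjoint, ordered")
        self.wear_schedule = sched

    def pti(self, condition: Condition) -> float:
        return (self.pti_in_device if condition is Condition.IN_DEVICE
                else self.pti_non_device)

    def ppp(self, condition: Condition) -> float:
        return (self.ppp_in_device if condition is Condition.IN_DEVICE
                else self.ppp_non_device)

    def tsr(self, condition: Condition) -> float | None:
        return (self.tsr_in_device if condition is Condition.IN_DEVICE
                else self.tsr_non_device)

    def start(self) -> np.datetime64:
        return np.datetime64(self.start_date, "ns")

    def wear_intervals_abs(self) -> list:
        """Absolute half-open wear intervals over the monitoring period."""
        out = []
        for d in range(self.monitoring_days):
            day = self.start() + np.timedelta64(d, "D")
            for on, off in self.wear_schedule:
                out.append((day + _h(on), day + _h(off)))
        return out

    def analytic_cpts(self) -> tuple[float, float | None]:
        """True daily CPTS (MPa.s/day) implied by the profile parameters."""
        s_in = self.true_adherence * self.true_daily_strides
        s_non = (1.0 - self.true_adherence) * self.true_daily_strides
        m1 = (self.pti_in_device * s_in + self.pti_non_device * s_non) / 1000.0
        m2 = None
        if self.tsr_in_device is not None and self.tsr_non_device is not None:
            m2 = (self.pti_in_device * s_in * self.tsr_in_device
                  + self.pti_non_device * s_non * self.tsr_non_device) / 1000.0
        return m1, m2


def _h(hours: float) -> np.timedelta64:
    return np.timedelta64(int(round(hours * 3600e9)), "ns")


# ------------------------------------------------------------------- config

def _iqr_range(style: str, key: str) -> tuple[float, float]:
    ref = factor_reference_ranges()[style][key]
    return (ref[1], ref[2])


@dataclass
class GenerationConfig:
    """Parameter ranges for profile generation (uniform draws within).

    Defaults are the published cohort IQRs per study style; a degenerate
    range [x, x] pins the parameter at x.
    """

    study_style: str = "au"
    adherence_range: tuple = (0.266, 0.687)
    daily_strides_range: tuple = (1015, 12456)
    pti_in_device_range: tuple = (60.0, 74.7)
    pti_non_device_range: tuple = (67.2, 86.3)
    ppp_in_device_range: tuple = (110.9, 302.7)
    ppp_non_device_range: tuple = (141.4, 236.4)
    tsr_in_device_range: tuple | None = (0.30, 1.07)
    tsr_non_device_range: tuple | None = (-0.15, 2.54)
    thermal: bool = True
    monitoring_days: int = 7
    wear_on_hour_range: tuple = (7.5, 9.0)
    wear_duration_h_range: tuple = (11.0, 13.0)
    healed_rate: float = 0.5
    healed_pti_scale: float = 0.75  # healed participants load the site less

    def __post_init__(self):
        for name in ("adherence_range", "daily_strides_range",
                     "pti_in_device_range", "pti_non_device_range",
                     "ppp_in_device_range", "ppp_non_device_range",
                     "tsr_in_device_range", "tsr_non_device_range",
                     "wear_on_hour_range", "wear_duration_h_range"):
            rng = getattr(self, name)
            if rng is not None and rng[0] > rng[1]:
                raise ConfigurationError(f"{name}: min {rng[0]} > max {rng[1]}")
        if not 0.0 <= self.adherence_range[0] and self.adherence_range[1] <= 1.0:
            raise ConfigurationError("adherence range must lie within [0, 1]")

    @classmethod
    def au_study(cls, **overrides) -> "GenerationConfig":
        base = dict(
            study_style="au", thermal=True,
            adherence_range=_iqr_range("au", "adherence"),
            daily_strides_range=_iqr_range("au", "daily_strides"),
            pti_in_device_range=_iqr_range("au", "pti_in_device"),
            pti_non_device_range=_iqr_range("au", "pti_non_device"),
            ppp_in_device_range=_iqr_range("au", "ppp_in_device"),
            ppp_non_device_range=_iqr_range("au", "ppp_non_device"),
            tsr_in_device_range=_iqr_range("au", "tsr_in_device"),
            tsr_non_device_range=_iqr_range("au", "tsr_non_device"),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def nl_study(cls, **overrides) -> "GenerationConfig":
        base = dict(
            study_style="nl", thermal=False,
            adherence_range=_iqr_range("nl", "adherence"),
            daily_strides_range=_iqr_range("nl", "daily_strides"),
            pti_in_device_range=_iqr_range("nl", "pti_in_device"),
            pti_non_device_range=_iqr_range("nl", "pti_non_device"),
            ppp_in_device_range=_iqr_range("nl", "ppp_in_device"),
            ppp_non_device_range=_iqr_range("nl", "ppp_non_device"),
            tsr_in_device_range=None, tsr_non_device_range=None,
        )
        base.update(overrides)
        return cls(**base)


def generate_profile(seed: int, config: GenerationConfig | None = None,
                     participant_id: str | None = None) -> ParticipantProfile:
    """Draw one participant profile; identical (seed, config) => identical profile."""
    config = config or GenerationConfig()
    rng = np.random.default_rng(seed)

    def u(rng_pair):
        return float(rng.uniform(rng_pair[0], rng_pair[1]))

    adherence = u(config.adherence_range)
    strides = int(round(u(config.daily_strides_range)))
    healed = bool(rng.random() < config.healed_rate)
    pti_scale = config.healed_pti_scale if healed else 1.0
    on = u(config.wear_on_hour_range)
    dur = u(config.wear_duration_h_range)
    off = min(24.0, on + dur)
    tsr_in = tsr_non = None
    if config.thermal:
        if config.tsr_in_device_range is None or config.tsr_non_device_range is None:
            raise ConfigurationError("thermal study style needs TSR ranges")
        tsr_in = u(config.tsr_in_device_range)
        tsr_non = u(config.tsr_non_device_range)
    return ParticipantProfile(
        id=participant_id or f"{config.study_style.upper()}{seed:05d}",
        true_adherence=adherence,
        true_daily_strides=max(1, strides),
        pti_in_device=u(config.pti_in_device_range) * pti_scale,
        pti_non_device=u(config.pti_non_device_range) * pti_scale,
        ppp_in_device=u(config.ppp_in_device_range) * pti_scale,
        ppp_non_device=u(config.ppp_non_device_range) * pti_scale,
        tsr_in_device=tsr_in, tsr_non_device=tsr_non,
        wear_schedule=[(on, off)],
        monitoring_days=config.monitoring_days,
        healed=healed, study_style=config.study_style,
    )


# -------------------------------------------------------------- temperature

def simulate_temperature_log(profile: ParticipantProfile, seed: int = 0,
                             noise_sd: float = 0.3,
                             skin_c: float = SKIN_SETPOINT_C,
                             ambient_c: float = AMBIENT_C,
                             tau_min: float = TAU_MIN,
                             initial_c: float | None = None) -> TemperatureLog:
    """In-device temperature sampled every 15 min over the monitoring period.

    Between samples the sensor relaxes first-order toward the skin set-point
    while the device is worn and toward ambient otherwise; the relaxation is
    integrated exactly across don/doff events.  Gaussian measurement noise
    is added to the recorded values only.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    start = profile.start()
    n_samples = profile.monitoring_days * 96
    sample_ts = start + np.arange(n_samples) * np.timedelta64(15, "m")

    transitions = []  # (time, is_on)
    for on_t, off_t in profile.wear_intervals_abs():
        transitions.append((on_t, True))
        transitions.append((off_t, False))
    transitions.sort(key=lambda p: p[0])

    temp = float(ambient_c if initial_c is None else initial_c)
    tau_ns = tau_min * 60e9
    worn = False
    ti = 0
    now = start
    out = np.empty(n_samples)
    for i, t_s in enumerate(sample_ts):
        while ti < len(transitions) and transitions[ti][0] <= t_s:
            t_ev, state = transitions[ti]
            if t_ev > now:
                target = skin_c if worn else ambient_c
                dt = (t_ev - now).astype("timedelta64[ns]").astype(float)
                temp = target + (temp - target) * np.exp(-dt / tau_ns)
                now = t_ev
            worn = state
            ti += 1
        if t_s > now:
            target = skin_c if worn else ambient_c
            dt = (t_s - now).astype("timedelta64[ns]").astype(float)
            temp = target + (temp - target) * np.exp(-dt / tau_ns)
            now = t_s
        out[i] = temp
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=n_samples)
    return TemperatureLog(timestamps=sample_ts, temps_c=out)


# ------------------------------------------------------------------ strides

def _region_slots(regions, cadence_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Flatten (start_s, end_s) regions into a slot grid at fixed cadence."""
    starts, counts = [], []
    for a, b in regions:
        k = int(np.floor((b - a) / cadence_s))
        if k > 0:
            starts.append(a)
            counts.append(k)
    return np.asarray(starts, float), np.asarray(counts, int)


def _place_in_bouts(rng, regions, m: int, cadence_s: float,
                    mean_bout: float) -> np.ndarray:
    """Choose m slot times grouped into bouts inside the given regions.

    Slots sit on a fixed cadence grid inside each region (last slot at least
    one cadence before the region end so merged streams keep their spacing).
    Bout lengths are Poisson(mean_bout); the gaps between bouts partition the
    unused slots multinomially.
    """
    if m == 0:
        return np.array([], dtype=float)
    starts, counts = _region_slots(regions, cadence_s)
    total = int(counts.sum())
    if m > total:
        raise InfeasibilityError(
            f"cannot place {m} strides in {total} available slots")
    runs = []
    remaining = m
    while remaining > 0:
        size = min(remaining, max(1, int(rng.poisson(mean_bout))))
        runs.append(size)
        remaining -= size
    gaps = rng.multinomial(total - m, np.full(len(runs) + 1, 1.0 / (len(runs) + 1)))
    slot_idx = []
    pos = int(gaps[0])
    for size, gap in zip(runs, gaps[1:]):
        slot_idx.extend(range(pos, pos + size))
        pos += size + int(gap)
    slot_idx = np.asarray(slot_idx, dtype=int)
    # map slot index -> absolute time
    bounds = np.concatenate([[0], np.cumsum(counts)])
    region_of = np.searchsorted(bounds, slot_idx, side="right") - 1
    within = slot_idx - bounds[region_of]
    return starts[region_of] + within * cadence_s


def simulate_stride_stream(profile: ParticipantProfile, seed: int = 0,
                           cadence_s: float = 1.1, mean_bout: float = 30.0,
                           day_cv: float = 0.01,
                           active_hours: tuple = (6.0, 24.0),
                           ) -> StrideEventSeries:
    """Stride events in bouts, split between wear and non-wear periods.

    Per day the stride count is drawn tightly around ``true_daily_strides``
    (coefficient of variation ``day_cv``); a fraction ``true_adherence`` of
    them (to rounding granularity) is placed inside the daily wear intervals,
    the rest in the waking non-wear windows.  No strides occur between 00:00
    and 06:00.
    """
    rng = np.random.default_rng(seed)
    a = profile.true_adherence
    if not profile.wear_schedule and a > 0:
        raise InfeasibilityError("positive adherence with empty wear schedule")
    act_lo, act_hi = (h * 3600.0 for h in active_hours)
    wear_s = [(on * 3600.0, off * 3600.0) for on, off in profile.wear_schedule]
    # waking time not covered by wear intervals
    out_regions = []
    cursor = act_lo
    for on, off in wear_s:
        if on > cursor:
            out_regions.append((cursor, min(on, act_hi)))
        cursor = max(cursor, off)
    if cursor < act_hi:
        out_regions.append((cursor, act_hi))
    in_regions = [(max(on, act_lo), min(off, act_hi)) for on, off in wear_s]
    in_regions = [r for r in in_regions if r[1] > r[0]]

    all_ts = []
    for d in range(profile.monitoring_days):
        day = profile.start() + np.timedelta64(d, "D")
        n = max(0, int(round(rng.normal(profile.true_daily_strides,
                                        day_cv * profile.true_daily_strides))))
        n_in = int(round(a * n))
        n_out = n - n_in
        if n_out > 0 and not out_regions:
            raise InfeasibilityError(
                "non-device strides requested but wear covers all waking hours")
        offsets = np.concatenate([
            _place_in_bouts(rng, in_regions, n_in, cadence_s, mean_bout),
            _place_in_bouts(rng, out_regions, n_out, cadence_s, mean_bout),
        ])
        offsets.sort()
        all_ts.append(day + (offsets * 1e9).astype("timedelta64[ns]"))
    ts = np.concatenate(all_ts) if all_ts else np.array([], dtype="datetime64[ns]")
    return StrideEventSeries(timestamps=ts, source="simulated")


# ------------------------------------------------------------- acceleration

def simulate_acceleration(strides: StrideEventSeries,
                          sampling_rate: float = 100.0, seed: int = 0,
                          window: tuple | None = None,
                          noise_sd: float = 0.02,
                          stride_amp_g: float = 0.8,
                          pulse_width_s: float = 0.06,
                          nonwear_windows: list | None = None,
                          ) -> AccelerationSeries:
    """Render stride events as a tri-axial trunk acceleration signal.

    The vertical channel carries 1 g gravity, small noise and one dominant
    Gaussian-shaped peak per stride; requested amplitudes beyond the device
    range are clipped at +/-6 g.  Optional ``nonwear_windows`` (pairs of
    timestamps) are near-zero-variance, emulating a monitor left on a table.
    """
    if sampling_rate <= 0:
        raise ConfigurationError("sampling_rate must be positive")
    if window is None:
        if len(strides) == 0:
            raise InputError("empty stride series needs an explicit window")
        pad = np.timedelta64(5, "s")
        window = (strides.timestamps[0] - pad, strides.timestamps[-1] + pad)
    start = np.datetime64(window[0], "ns")
    end = np.datetime64(window[1], "ns")
    n = int(np.floor((end - start).astype("timedelta64[ns]").astype(float)
                     / 1e9 * sampling_rate)) + 1
    rng = np.random.default_rng(seed)
    t = np.arange(n) / sampling_rate
    az = 1.0 + rng.normal(0.0, noise_sd, n)
    ax = rng.normal(0.0, noise_sd * 0.5, n)
    ay = rng.normal(0.0, noise_sd * 0.5, n)
    ev = (strides.timestamps - start).astype("timedelta64[ns]").astype(float) / 1e9
    ev = ev[(ev >= 0) & (ev <= t[-1])]
    half = int(np.ceil(4 * pulse_width_s * sampling_rate))
    for e in ev:
        c = int(round(e * sampling_rate))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        az[lo:hi] += stride_amp_g * np.exp(
            -0.5 * ((t[lo:hi] - e) / pulse_width_s) ** 2)
    data = np.column_stack([ax, ay, az])
    for w0, w1 in (nonwear_windows or []):
        i0 = int(max(0, np.floor((np.datetime64(w0, "ns") - start)
                                 .astype("timedelta64[ns]").astype(float)
                                 / 1e9 * sampling_rate)))
        i1 = int(min(n, np.ceil((np.datetime64(w1, "ns") - start)
                                .astype("timedelta64[ns]").astype(float)
                                / 1e9 * sampling_rate)))
        data[i0:i1] = rng.normal(0.0, 1e-4, (max(0, i1 - i0), 3))
    np.clip(data, -DEVICE_CLIP_G, DEVICE_CLIP_G, out=data)
    return AccelerationSeries(sampling_rate=sampling_rate, start=start, data=data)


# ----------------------------------------------------------------- pressure

def insole_geometry() -> tuple[np.ndarray, float, list[str]]:
    """99-sensor insole layout: 15 x 7 grid minus corner pads, 2 cm^2 each."""
    rows, cols = 15, 7
    pitch_x, pitch_y = 14.0, 17.0
    pts = [(c * pitch_x, r * pitch_y) for r in range(rows) for c in range(cols)]
    # drop six corner pads to shape a 99-sensor outline
    drop = {0, 6, 7 * 14, 7 * 14 + 6, 7 * 14 + 1, 7 * 14 + 5}
    pts = [p for i, p in enumerate(pts) if i not in drop]
    ids = [f"sensor_{i:03d}" for i in range(len(pts))]
    return np.asarray(pts, float), 2.0, ids


# forefoot pads under a typical plantar ulcer site
INSOLE_ULCER_SENSOR_IDS = ["sensor_073", "sensor_074", "sensor_080", "sensor_081"]


def platform_geometry(nx: int = 30, ny: int = 16) -> tuple[np.ndarray, float, list[str]]:
    """Pressure platform: 5 mm pitch grid (4 sensors/cm^2), 0.25 cm^2 cells."""
    pitch = 5.0
    pts = [(x * pitch, y * pitch) for y in range(ny) for x in range(nx)]
    ids = [f"sensor_{i:03d}" for i in range(len(pts))]
    return np.asarray(pts, float), 0.25, ids


PLATFORM_ULCER_CENTER_MM = (100.0, 40.0)


def simulate_pressure_trial(profile: ParticipantProfile, condition: Condition,
                            n_steps: int, dialect: str, seed: int = 0,
                            noise_sd: float = 0.0, swing_s: float = 0.5,
                            ) -> PressureFrameSeries:
    """Pressure trial whose stances are analytic half-sine pulses.

    Peak P equals the profile's PPP target for the condition; stance duration
    T = pi * PTI / (2 P) realises the PTI target, rounded to an even number
    of samples so a frame lands exactly on the pulse peak.  The per-step
    analytic PTI actually constructed, 2 P T / pi, is recorded in
    ``meta["analytic_step_pti"]``.  Ulcer-mask sensors carry the full pulse;
    a ring of neighbouring sensors carries 40% of it; swing phases are zero.
    """
    pti_target = profile.pti(condition)
    ppp_target = profile.ppp(condition)
    if pti_target <= 0:
        raise ConfigurationError("target PTI must be positive")
    if n_steps < 1:
        raise ConfigurationError("n_steps must be >= 1")
    if dialect == "insole":
        fs = 50.0
        geometry, area, ids = insole_geometry()
        mask_ids = INSOLE_ULCER_SENSOR_IDS
    elif dialect == "platform":
        if n_steps != 1:
            raise ConfigurationError("platform trials hold one contact each")
        fs = 100.0
        geometry, area, ids = platform_geometry()
        d = np.linalg.norm(geometry - np.asarray(PLATFORM_ULCER_CENTER_MM), axis=1)
        mask_ids = [ids[i] for i in np.nonzero(d <= 10.0)[0]]
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    dt = 1.0 / fs
    T = np.pi * pti_target / (2.0 * ppp_target)  # exact: PTI = 2 P T / pi

    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(ids)}
    mask_idx = np.array([idx[s] for s in mask_ids])
    # neighbours within 25 mm of the mask get a 40% background pulse
    centre = geometry[mask_idx].mean(axis=0)
    ring = np.nonzero((np.linalg.norm(geometry - centre, axis=1) <= 25.0))[0]
    ring = np.setdiff1d(ring, mask_idx)

    # one frame lands exactly on each pulse peak; the stance itself may start
    # between frames so T (and hence the analytic PTI) stays exact
    step_span = int(np.ceil((T + swing_s) * fs))
    first_peak = int(np.ceil((swing_s + T / 2.0) * fs))
    peak_idx = first_peak + step_span * np.arange(n_steps)
    n_frames = int(peak_idx[-1] + np.ceil((T / 2.0 + swing_s) * fs)) + 1
    frames = np.zeros((n_frames, geometry.shape[0]))
    starts = []
    for c in peak_idx:
        t_start = c * dt - T / 2.0
        j0 = int(np.floor(t_start / dt)) + 1
        j1 = int(np.ceil((t_start + T) / dt)) - 1
        t_rel = np.arange(j0, j1 + 1) * dt - t_start
        pulse = ppp_target * np.sin(np.pi * t_rel / T)
        frames[j0:j1 + 1, mask_idx] += pulse[:, None]
        if ring.size:
            frames[j0:j1 + 1, ring] += 0.4 * pulse[:, None]
        starts.append(float(t_start))
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if noise_sd > 0:
        frames = np.clip(frames + rng.normal(0, noise_sd, frames.shape), 0, None)
    return PressureFrameSeries(
        dialect=dialect, sampling_rate=fs,
        times=np.arange(n_frames) * dt, frames=frames,
        geometry=geometry, sensor_area_cm2=area, sensor_ids=ids,
        meta={
            "condition": condition.value,
            "analytic_step_pti": halfsine_pti(ppp_target, T),
            "peak_kpa": ppp_target, "stance_duration_s": T,
            "stance_start_times_s": starts, "participant": profile.id,
        },
    )


# ------------------------------------------------------------------ thermal

def simulate_thermal_pair(profile: ParticipantProfile, condition: Condition,
                          seed: int = 0, noise_sd: float = 0.0,
                          index_pre_c: float = 30.0, contra_pre_c: float = 30.0,
                          contra_rel_change: float = 0.05,
                          ) -> ThermalReadingPair:
    """Pre/post thermal ROI pair realising the profile's target TSR.

    Noise-free, evaluating the TSR ratio on the returned pair reproduces the
    target exactly; with noise, Gaussian perturbations are added to all four
    temperatures.
    """
    target = profile.tsr(condition)
    if target is None:
        raise ConfigurationError(
            f"profile {profile.id} carries no TSR target for {condition.value}")
    if contra_rel_change == 0 and np.isfinite(target):
        raise InfeasibilityError(
            "zero contralateral change cannot realise a finite TSR")
    rng = np.random.default_rng(seed)
    index_post = index_pre_c * (1.0 + contra_rel_change * target)
    contra_post = contra_pre_c * (1.0 + contra_rel_change)
    vals = np.array([index_pre_c, index_post, contra_pre_c, contra_post])
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, 4)
    return ThermalReadingPair(condition=condition, index_pre=vals[0],
                              index_post=vals[1], contra_pre=vals[2],
                              contra_post=vals[3])


# ------------------------------------------------------------------- cohort

@dataclass
class GroundTruthManifest:
    """True cohort parameters for parameter-recovery testing."""

    profiles: list
    seed: int
    config_digest: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [p.id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise InputError("participant ids must be unique")

    def profile(self, pid: str) -> ParticipantProfile:
        for p in self.profiles:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_digest": self.config_digest,
            "profiles": [asdict(p) for p in self.profiles],
            "extra": self.extra,
        }

    def digest(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruthManifest":
        profiles = [ParticipantProfile(**{**p, "wear_schedule":
                                          [tuple(w) for w in p["wear_schedule"]]})
                    for p in d["profiles"]]
        return cls(profiles=profiles, seed=d["seed"],
                   config_digest=d["config_digest"], extra=d.get("extra", {}))


def _config_digest(configs) -> str:
    payload = json.dumps([asdict(c) for c in configs], sort_keys=True,
                         default=float)
    return hashlib.sha256(payload.encode()).hexdigest()


def generate_cohort(n: int, seed: int, out_dir,
                    configs: list | GenerationConfig | None = None,
                    n_au: int | None = None,
                    noise_sd_temperature: float = 0.3,
                    noise_sd_thermal: float = 0.0,
                    n_walking_steps: int = 16,
                    ) -> GroundTruthManifest:
    """Generate a cohort and write all streams plus the truth manifest.

    Participants follow AU-style (thermal imaging, insole for both pressure
    conditions) or NL-style (no thermal, barefoot platform 2-step protocol
    for the non-device condition) configurations.  ``configs`` may be a
    single config for everyone or an explicit per-participant list; by
    default the first ``n_au`` (half, rounded up) are AU-style and the rest
    NL-style.  Deterministic: the same (n, seed, configs) reproduces
    byte-identical files and manifest digest.
    """
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}")
    if isinstance(configs, GenerationConfig):
        configs = [configs] * n
    elif configs is None:
        if n_au is None:
            n_au = (n + 1) // 2
        configs = [GenerationConfig.au_study()] * n_au \
            + [GenerationConfig.nl_study()] * (n - n_au)
    if len(configs) != n:
        raise ConfigurationError("need one config per participant")

    child = np.random.SeedSequence(seed).generate_state(4 * n) & 0x7FFFFFFF
    profiles = []
    for i, cfg in enumerate(configs):
        pid = f"{cfg.study_style.upper()}{i + 1:03d}"
        profile = generate_profile(int(child[4 * i]), cfg, participant_id=pid)
        profiles.append(profile)
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        strides = simulate_stride_stream(profile, seed=int(child[4 * i + 1]))
        cio.write_strides_csv(strides, pdir / "strides.csv")
        log = simulate_temperature_log(profile, seed=int(child[4 * i + 2]),
                                       noise_sd=noise_sd_temperature)
        cio.write_temperature_csv(log, pdir / "temperature.csv")
        pseed = int(child[4 * i + 3])
        trial_in = simulate_pressure_trial(profile, Condition.IN_DEVICE,
                                           n_walking_steps, "insole", seed=pseed)
        cio.write_pressure_csv(trial_in, pdir / "pressure_in_device.csv")
        if cfg.study_style == "nl":
            for j in range(4):
                trial = simulate_pressure_trial(profile, Condition.NON_DEVICE,
                                                1, "platform", seed=pseed + j + 1)
                cio.write_pressure_csv(
                    trial, pdir / f"pressure_non_device_trial{j + 1}.csv")
        else:
            trial_non = simulate_pressure_trial(profile, Condition.NON_DEVICE,
                                                n_walking_steps, "insole",
                                                seed=pseed + 1)
            cio.write_pressure_csv(trial_non, pdir / "pressure_non_device.csv")
        if cfg.thermal:
            pairs = [simulate_thermal_pair(profile, c, seed=pseed + 10,
                                           noise_sd=noise_sd_thermal)
                     for c in (Condition.IN_DEVICE, Condition.NON_DEVICE)]
            cio.write_thermal_json(pairs, pdir / "thermal.json")

    manifest = GroundTruthManifest(profiles=profiles, seed=seed,
                                   config_digest=_config_digest(configs))
    cio.write_json(manifest.to_json_dict(), out_dir / "manifest.json")
    return manifest
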