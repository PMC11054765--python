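"""Shared in-memory containers for the four sensor streams and derived series.

All timestamps are naive ``numpy.datetime64[ns]`` values on the participant's
local clock; every fusion step (stride classification, day binning) happens in
that single clock, with day boundaries at local midnight.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "Condition",
    "PressureFrameSeries",
    "StrideEventSeries",
    "TemperatureLog",
    "AccelerationSeries",
    "ThermalReadingPair",
    "WearIntervalSet",
]


class Condition(str, Enum):
    """Foot condition: walking in the offloading device or without it.

    "non-device" is regular footwear in the insole dialect and barefoot in
    the platform dialect.
    """

    IN_DEVICE = "in_device"
    NON_DEVICE = "non_device"


@dataclass
class PressureFrameSeries:
    """Time-ordered per-sensor plantar pressure frames.

    Parameters
    ----------
    dialect : {"insole", "platform"}
        Insole: in-shoe capacitive array sampled at 50 Hz during a walking
        trial.  Platform: floor-mounted grid at 100 Hz, one foot contact per
        trial (2-step protocol).
    sampling_rate : float
        Frames per second (Hz).
    times : ndarray of float
        Frame times in seconds from trial start, strictly increasing.
    frames : ndarray, shape (n_frames, n_sensors)
        Pressure per sensor in kPa, non-negative.
    geometry : ndarray, shape (n_sensors, 2)
        Sensor centre positions in mm.
    sensor_area_cm2 : float or ndarray
        Active area per sensor in cm^2 (scalar or per-sensor).
    sensor_ids : list of str
        Stable sensor identifiers (``sensor_000`` ...).
    """

    dialect: str
    sampling_rate: float
    times: np.ndarray
    frames: np.ndarray
    geometry: np.ndarray
    sensor_area_cm2: np.ndarray | float
    sensor_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        self.geometry = np.asarray(self.geometry, dtype=float)
        if self.dialect not in ("insole", "platform"):
            raise InputError(f"unknown pressure dialect {self.dialect!r}")
        if self.frames.ndim != 2 or self.frames.shape[1] != self.geometry.shape[0]:
            raise InputError("frame width must equal sensor count")
        if self.frames.shape[0] != self.times.shape[0]:
            raise InputError("times and frames must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InputError("frame times must be strictly increasing")
        if np.any(self.frames < 0):
            raise InputError("pressures must be non-negative")
        if len(self.sensor_ids) != self.geometry.shape[0]:
            raise InputError("sensor_ids must match geometry")

    @property
    def n_sensors(self) -> int:
        return self.geometry.shape[0]

    def total_force_newton(self) -> np.ndarray:
        """Per-frame total normal force in N (kPa * cm^2 * 0.1 = N)."""
        area = np.broadcast_to(np.asarray(self.sensor_area_cm2, dtype=float),
                               (self.n_sensors,))
        return (self.frames * area).sum(axis=1) * 0.1


@dataclass
class StrideEventSeries:
    """Ordered absolute stride timestamps with a provenance tag.

    A stride is one full gait cycle of a limb; inter-stride intervals below
    0.4 s are physiologically implausible and rejected.
    """

    timestamps: np.ndarray  # datetime64[ns], strictly increasing
    source: str = "detected"  # "detected" | "simulated"

    MIN_INTERVAL_S = 0.4

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        if self.timestamps.size > 1:
            gaps = np.diff(self.timestamps).astype("timedelta64[ns]").astype(float) / 1e9
            if np.any(gaps < self.MIN_INTERVAL_S - 1e-9):
                raise InputError(
                    "stride intervals below 0.4 s (min %.3f s)" % gaps.min()
                )

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def dates(self) -> np.ndarray:
        """Calendar date (day boundary at local midnight) of each stride."""
        return self.timestamps.astype("datetime64[D]")

    def per_day_counts(self) -> pd.Series:
        if len(self) == 0:
            return pd.Series(dtype=int)
        return pd.Series(1, index=self.dates()).groupby(level=0).sum()


@dataclass
class TemperatureLog:
    """In-device temperature samples at nominal 15-min spacing; gaps allowed."""

    timestamps: np.ndarray  # datetime64[ns]
    temps_c: np.ndarray
    NOMINAL_SPACING_MIN = 15.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        self.temps_c = np.asarray(self.temps_c, dtype=float)
        if self.timestamps.size != self.temps_c.size:
            raise InputError("timestamps and temperatures must align")
        if self.timestamps.size == 0:
            raise InputError("empty temperature log")
        spacings = self.spacings_min()
        if np.any(spacings <= 0):
            raise InputError("temperature timestamps must be increasing")
        # spacing must be a multiple of 15 min within 1-min tolerance
        off = np.abs(spacings / self.NOMINAL_SPACING_MIN
                     - np.round(spacings / self.NOMINAL_SPACING_MIN))
        if np.any(off * self.NOMINAL_SPACING_MIN > 1.0):
            raise InputError("temperature spacing not a multiple of 15 min")

    def spacings_min(self) -> np.ndarray:
        return np.diff(self.timestamps).astype("timedelta64[s]").astype(float) / 60.0

    def gaps(self, max_gap_h: float = 2.0) -> list[tuple[np.datetime64, np.datetime64]]:
        """Intervals between consecutive samples further apart than max_gap_h."""
        sp = self.spacings_min()
        idx = np.nonzero(sp > max_gap_h * 60.0)[0]
        return [(self.timestamps[i], self.timestamps[i + 1]) for i in idx]


@dataclass
class AccelerationSeries:
    """Tri-axial trunk acceleration in g, clipped to +/-6 g by the device."""

    sampling_rate: float
    start: np.datetime64
    data: np.ndarray  # shape (n, 3): ax, ay, az in g

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.start = np.datetime64(self.start, "ns")
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise InputError("acceleration data must be (n, 3)")
        if np.any(np.abs(self.data) > 6.0 + 1e-9):
            raise InputError("acceleration outside the +/-6 g device range")

    def __len__(self) -> int:
        return int(self.data.shape[0])

    def times_s(self) -> np.ndarray:
        return np.arange(len(self)) / self.sampling_rate

    def timestamps(self) -> np.ndarray:
        offs = (np.arange(len(self)) / self.sampling_rate * 1e9).astype("timedelta64[ns]")
        return self.start + offs

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=1)


@dataclass
class ThermalReadingPair:
    """Pre/post-walk ROI temperatures for index and contralateral foot (deg C)."""

    condition: Condition
    index_pre: float
    index_post: float
    contra_pre: float
    contra_post: float

    def __post_init__(self):
        vals = (self.index_pre, self.index_post, self.contra_pre, self.contra_post)
        if not all(np.isfinite(v) for v in vals):
            raise InputError("thermal readings must be finite")


@dataclass
class WearIntervalSet:
    """Disjoint ordered half-open [on, off) device-wear intervals.

    ``span`` records the extent of the source log so that strides outside it
    can be flagged as uncovered rather than silently classed as non-device.
    """

    intervals: list  # [(datetime64, datetime64), ...]
    algorithm: str = "manual"
    params: dict = field(default_factory=dict)
    span: tuple | None = None  # (start, end) of the source record
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        iv = [(np.datetime64(a, "ns"), np.datetime64(b, "ns"))
              for a, b in self.intervals]
        iv.sort(key=lambda p: p[0])
        for on, off in iv:
            if not on < off:
                raise InputError("wear interval must satisfy on < off")
        for (_, off0), (on1, _) in zip(iv, iv[1:]):
            if on1 < off0:
                raise InputError("wear intervals must be disjoint")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, timestamps: np.ndarray) -> np.ndarray:
        """Vectorised membership under the half-open [on, off) convention."""
        ts = np.asarray(timestamps, dtype="datetime64[ns]")
        if not self.intervals:
            return np.zeros(ts.shape, dtype=bool)
        ons = np.array([a for a, _ in self.intervals], dtype="datetime64[ns]")
        offs = np.array([b for _, b in self.intervals], dtype="datetime64[ns]")
        # index of the last interval whose `on` is <= ts
        idx = np.searchsorted(ons, ts, side="right") - 1
        inside = idx >= 0
        inside[inside] = ts[inside] < offs[idx[inside]]
        return inside

    def total_hours(self) -> float:
        ns = sum((b - a).astype("timedelta64[ns]").astype(float)
                 for a, b in self.intervals)
        return ns / 3600e9

    def shifted(self, delta: np.timedelta64) -> "WearIntervalSet":
        return WearIntervalSet(
            [(a + delta, b + delta) for a, b in self.intervals],
            algorithm=self.algorithm, params=dict(self.params),
            span=None if self.span is None
            else (self.span[0] + delta, self.span[1] + delta),
        )
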