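"""Daily weight-bearing activity from trunk accelerometry or stride events.

The trunk monitor records tri-axial acceleration at 100 Hz (+/-6 g).  Two
stand-in algorithms operate on it (the vendor's stride algorithm and its
wear-time rule are proprietary; these stand-ins are validated only against
synthetic ground truth):

- monitor wear: windows where the standard deviation of the acceleration
  magnitude exceeds a threshold (a worn trunk sensor is never perfectly
  still; one lying on a table is);
- stride detection: peak picking on the band-passed (0.5-3 Hz) vertical
  channel with a 0.4 s minimum inter-stride distance.

A monitoring day is *valid* with >= 12 h of monitor wear; >= 4 valid days are
required, otherwise the participant is non-adherent to the measurement
protocol.  Daily weight-bearing activity is the stride count per day averaged
over valid days.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InputError, NonAdherentError
from .types import AccelerationSeries, StrideEventSeries

__all__ = ["DailyActivity", "detect_monitor_wear", "detect_strides",
           "daily_activity"]

MIN_WEAR_HOURS = 12.0
MIN_VALID_DAYS = 4


@dataclass
class DailyActivity:
    date: np.datetime64
    stride_count: int
    monitor_wear_hours: float
    valid: bool


def detect_monitor_wear(accel: AccelerationSeries, window_s: float = 60.0,
                        std_threshold_g: float = 0.02) -> list[tuple]:
    """Wear intervals of the trunk monitor from movement variance.

    The record is cut into non-overlapping windows; a window is "worn" when
    the standard deviation of the acceleration magnitude reaches the
    threshold.  Adjacent worn windows are merged.  A zero threshold
    degenerates to the whole record.
    """
    if window_s <= 0:
        raise InputError("window must be positive")
    if len(accel) == 0:
        raise InputError("empty acceleration series")
    n_per = max(1, int(round(window_s * accel.sampling_rate)))
    mag = accel.magnitude()
    n_win = int(np.ceil(len(mag) / n_per))
    worn = np.empty(n_win, dtype=bool)
    for w in range(n_win):
        worn[w] = mag[w * n_per:(w + 1) * n_per].std() >= std_threshold_g
    step_ns = np.timedelta64(int(round(n_per / accel.sampling_rate * 1e9)), "ns")
    record_end = accel.start + np.timedelta64(
        int(round(len(mag) / accel.sampling_rate * 1e9)), "ns")
    intervals = []
    padded = np.concatenate([[False], worn, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for s, e in zip(edges[::2], edges[1::2]):
        start = accel.start + s * step_ns
        end = min(accel.start + e * step_ns, record_end)
        intervals.append((start, end))
    return intervals


def detect_strides(accel: AccelerationSeries,
                   band_hz: tuple[float, float] = (0.5, 3.0),
                   min_distance_s: float = 0.4,
                   prominence_g: float = 0.2) -> StrideEventSeries:
    """Stand-in stride detector: band-passed vertical-channel peak picking.

    Returns one event per dominant vertical peak.  Requires at least 20 Hz
    sampling so the gait band is resolvable.
    """
    if accel.sampling_rate < 20:
        raise InputError("stride detection needs >= 20 Hz sampling")
    if len(accel) == 0:
        return StrideEventSeries(np.array([], dtype="datetime64[ns]"),
                                 source="detected")
    az = accel.data[:, 2]
    nyq = accel.sampling_rate / 2.0
    sos = signal.butter(4, [band_hz[0] / nyq, band_hz[1] / nyq],
                        btype="band", output="sos")
    filtered = signal.sosfiltfilt(sos, az)
    peaks, _ = signal.find_peaks(
        filtered,
        distance=max(1, int(round(min_distance_s * accel.sampling_rate))),
        prominence=prominence_g,
    )
    offs = (peaks / accel.sampling_rate * 1e9).astype("timedelta64[ns]")
    return StrideEventSeries(accel.start + offs, source="detected")


def _interval_hours_by_day(intervals, dates: np.ndarray) -> pd.Series:
    """Hours of interval coverage falling on each calendar date."""
    hours = pd.Series(0.0, index=pd.Index(dates, name="date"))
    for start, end in intervals:
        start = np.datetime64(start, "ns")
        end = np.datetime64(end, "ns")
        day = start.astype("datetime64[D]")
        while day < end:
            nxt = day + np.timedelta64(1, "D")
            lo = max(start, day.astype("datetime64[ns]"))
            hi = min(end, nxt.astype("datetime64[ns]"))
            if hi > lo and day in hours.index:
                hours[day] += (hi - lo).astype("timedelta64[s]").astype(float) / 3600.0
            day = nxt
    return hours


def daily_activity(strides: StrideEventSeries,
                   monitor_wear: list | None = None,
                   min_wear_h: float = MIN_WEAR_HOURS,
                   min_valid_days: int = MIN_VALID_DAYS,
                   ) -> tuple[pd.DataFrame, float]:
    """Per-day stride counts, wear hours and validity; mean over valid days.

    ``monitor_wear`` is a list of (start, end) monitor-wear intervals.  When
    the activity source is a pre-extracted stride-event file (no raw
    accelerometry), pass None: daily wear is then approximated by the
    first-to-last-stride span of the day, a documented stand-in.

    Returns (DataFrame indexed by date with columns stride_count, wear_h,
    valid; mean strides/day over valid days).  Raises
    :class:`NonAdherentError` when fewer than ``min_valid_days`` days are
    valid.
    """
    if len(strides) == 0:
        raise NonAdherentError(0, min_valid_days)
    counts = strides.per_day_counts()
    all_days = set(counts.index.to_numpy(dtype="datetime64[D]"))
    for start, end in (monitor_wear or []):
        day = np.datetime64(start, "ns").astype("datetime64[D]")
        last = np.datetime64(end, "ns").astype("datetime64[D]")
        while day <= last:
            all_days.add(day)
            day += np.timedelta64(1, "D")
    index = pd.Index(sorted(all_days), name="date")
    counts = counts.reindex(index).fillna(0)
    dates = index.to_numpy(dtype="datetime64[D]")
    if monitor_wear is None:
        # span of activity per day as a wear proxy
        ts = strides.timestamps
        wear_h = pd.Series(0.0, index=counts.index)
        for d in dates:
            sel = ts[(ts >= d) & (ts < d + np.timedelta64(1, "D"))]
            if sel.size:
                wear_h[d] = (sel.max() - sel.min()).astype(
                    "timedelta64[s]").astype(float) / 3600.0
    else:
        wear_h = _interval_hours_by_day(monitor_wear, dates)
    df = pd.DataFrame({
        "stride_count": counts.astype(int),
        "wear_h": wear_h.reindex(counts.index).fillna(0.0),
    })
    df["valid"] = df["wear_h"] >= min_wear_h
    n_valid = int(df["valid"].sum())
    if n_valid < min_valid_days:
        raise NonAdherentError(n_valid, min_valid_days)
    mean_strides = float(df.loc[df["valid"], "stride_count"].mean())
    return df, mean_strides
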