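"""Device-wear intervals from temperature logs and stride classification.

An in-device temperature sensor logs every 15 min.  Donning drives the
reading from ambient toward skin temperature, doffing back toward ambient, so
wear episodes appear as warm plateaus bracketed by first-order transients.
The published wear-time algorithm for these sensors is external to this
package; the stand-in here is a hysteresis detector with slope assistance:

- wear starts at the first sample with temp >= on_threshold, or with
  temp >= off_threshold while rising by >= min_slope per sample;
- wear ends at the first sample with temp < off_threshold, or with
  temp < on_threshold while falling by >= min_slope per sample;
- a boundary triggered by a slope is back-dated one sample: a first-order
  sensor shows its largest transient in the first interval after the
  don/doff event, so the event lies closer to the preceding sample.

Intervals snap to sample timestamps (15-min quantisation).  Log gaps longer
than 2 h split any spanning wear interval and are recorded as warnings.

Each stride is then classed in-device iff its timestamp falls in a half-open
[on, off) wear interval; adherence is the percentage of in-device strides
over all strides on valid monitoring days.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedAdherenceError
from .types import StrideEventSeries, TemperatureLog, WearIntervalSet

__all__ = ["AdherenceSummary", "wear_intervals_from_temperature",
           "classify_strides", "adherence_percent"]

ON_THRESHOLD_C = 27.0
OFF_THRESHOLD_C = 25.0
MIN_SLOPE_C = 0.5          # per 15-min sample
MAX_GAP_H = 2.0


@dataclass
class AdherenceSummary:
    adherence_percent: float      # over valid days
    per_day: pd.DataFrame         # date-indexed in_device / non_device / valid
    n_strides_in: int
    n_strides_total: int


def wear_intervals_from_temperature(log: TemperatureLog,
                                    on_threshold: float = ON_THRESHOLD_C,
                                    off_threshold: float = OFF_THRESHOLD_C,
                                    min_slope: float = MIN_SLOPE_C,
                                    max_gap_h: float = MAX_GAP_H,
                                    ) -> WearIntervalSet:
    """Extract device-wear intervals from a 15-min temperature log."""
    if not on_threshold > off_threshold:
        raise InputError("hysteresis requires on_threshold > off_threshold")
    ts, temp = log.timestamps, log.temps_c
    gap_ns = np.timedelta64(int(max_gap_h * 3600e9), "ns")
    intervals: list[tuple] = []
    warnings: list[str] = []

    def run_base(k: int, lo: int, sign: float) -> int:
        # first sample of the contiguous rising (sign=+1) / falling (sign=-1)
        # run ending at sample k: the don/doff event sits at its base, since
        # the first-order transient starts immediately after the transition
        j = k
        while j - 1 > lo and sign * (temp[j] - temp[j - 1]) >= min_slope:
            j -= 1
        return j

    wearing = temp[0] >= on_threshold
    start_idx = 0 if wearing else -1
    boundary = 0  # index before which back-tracking must stop
    for k in range(1, ts.size):
        if ts[k] - ts[k - 1] > gap_ns:
            if wearing:
                intervals.append((ts[start_idx], ts[k - 1]))
                warnings.append(
                    f"log gap > {max_gap_h:g} h at {ts[k - 1]} splits wear interval"
                )
                wearing = False
            boundary = k
            # state restarts cold after the gap
            if temp[k] >= on_threshold:
                wearing, start_idx = True, k
            continue
        delta = temp[k] - temp[k - 1]
        if not wearing:
            if temp[k] >= on_threshold or (temp[k] >= off_threshold
                                           and delta >= min_slope):
                wearing = True
                start_idx = run_base(k, boundary, +1.0)
        else:
            if temp[k] < off_threshold or (temp[k] < on_threshold
                                           and -delta >= min_slope):
                end_idx = max(run_base(k, start_idx, -1.0), start_idx + 1)
                intervals.append((ts[start_idx], ts[end_idx]))
                boundary = k
                wearing = False
    if wearing:
        intervals.append((ts[start_idx], ts[-1] + np.timedelta64(15, "m")))
    intervals = [(a, b) for a, b in intervals if b > a]
    return WearIntervalSet(
        intervals, algorithm="hysteresis_slope_standin",
        params={"on_threshold": on_threshold, "off_threshold": off_threshold,
                "min_slope": min_slope, "max_gap_h": max_gap_h},
        span=(ts[0], ts[-1]), warnings=warnings,
    )


def classify_strides(strides: StrideEventSeries, wear: WearIntervalSet,
                     ) -> pd.DataFrame:
    """Per-day in-device / non-device stride partition.

    A stride is in-device iff its timestamp lies in some half-open [on, off)
    interval; strides outside the temperature log's span are counted
    non-device and flagged in the frame's ``attrs["coverage_warning"]``.
    The two columns always sum to the day's total stride count.
    """
    ts = strides.timestamps
    inside = wear.contains(ts)
    uncovered = 0
    if wear.span is not None and ts.size:
        covered = (ts >= wear.span[0]) & (ts <= wear.span[1])
        uncovered = int((~covered).sum())
    dates = ts.astype("datetime64[D]")
    df = pd.DataFrame({"date": dates, "in_device": inside})
    out = df.groupby("date")["in_device"].agg(["sum", "count"])
    result = pd.DataFrame({
        "in_device": out["sum"].astype(int),
        "non_device": (out["count"] - out["sum"]).astype(int),
    })
    result.index.name = "date"
    result.attrs["coverage_warning"] = (
        f"{uncovered} strides outside the temperature log span" if uncovered else None
    )
    return result


def adherence_percent(counts: pd.DataFrame, valid_days=None) -> AdherenceSummary:
    """Adherence = 100 * in-device strides / total strides over valid days.

    ``valid_days`` is an iterable of dates (defaults to all days present).
    Raises :class:`UndefinedAdherenceError` when the valid days carry no
    strides at all.
    """
    df = counts.copy()
    if valid_days is None:
        df["valid"] = True
    else:
        valid_set = {np.datetime64(d, "D") for d in valid_days}
        df["valid"] = [np.datetime64(d, "D") in valid_set for d in df.index]
    sel = df[df["valid"]]
    total = int(sel["in_device"].sum() + sel["non_device"].sum())
    if total == 0:
        raise UndefinedAdherenceError("no strides on valid days")
    n_in = int(sel["in_device"].sum())
    return AdherenceSummary(
        adherence_percent=100.0 * n_in / total,
        per_day=df, n_strides_in=n_in, n_strides_total=total,
    )
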