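"""Readers and writers for the package's documented stream dialects.

All formats are plain text so that runs are auditable and diffable:

- pressure CSV: ``# key=value`` metadata header lines (dialect, sampling
  rate, sensor area, geometry as JSON) then ``time_s,sensor_000,...``;
- acceleration CSV: metadata header then ``time_s,ax_g,ay_g,az_g``;
- temperature CSV: ``timestamp_iso,temp_c``;
- stride-event CSV: ``timestamp_iso`` (one event per row);
- thermal JSON: list of {condition, foot, pre_c, post_c} records;
- wear-interval JSON, daily-activity CSV, per-participant results JSON.

Proprietary device exports are out of scope; only these dialects are parsed.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InputError
from .types import (AccelerationSeries, Condition, PressureFrameSeries,
                    StrideEventSeries, TemperatureLog, ThermalReadingPair)

__all__ = [
    "read_stream",
    "write_pressure_csv", "read_pressure_csv",
    "write_acceleration_csv", "read_acceleration_csv",
    "write_temperature_csv", "read_temperature_csv",
    "write_strides_csv", "read_strides_csv",
    "write_thermal_json", "read_thermal_json",
    "write_wear_json", "write_json",
]

_TS_FMT = "%Y-%m-%dT%H:%M:%S.%f"


def _iso(ts) -> str:
    return pd.Timestamp(ts).strftime(_TS_FMT)


def _meta_header(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _read_meta(path: Path) -> tuple[dict, int]:
    meta, n = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
            n += 1
    return meta, n


# ---------------------------------------------------------------- pressure

def write_pressure_csv(series: PressureFrameSeries, path) -> None:
    path = Path(path)
    area = np.broadcast_to(np.asarray(series.sensor_area_cm2, float),
                           (series.n_sensors,))
    meta = {
        "stream": "pressure",
        "dialect": series.dialect,
        "sampling_rate_hz": repr(float(series.sampling_rate)),
        "sensor_area_cm2": json.dumps(np.round(area, 6).tolist()),
        "geometry_mm": json.dumps(np.round(series.geometry, 3).tolist()),
        "sensor_ids": json.dumps(series.sensor_ids),
        "meta": json.dumps(series.meta, sort_keys=True, default=float),
    }
    df = pd.DataFrame(series.frames, columns=series.sensor_ids)
    df.insert(0, "time_s", series.times)
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        df.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def read_pressure_csv(path) -> PressureFrameSeries:
    path = Path(path)
    meta, skip = _read_meta(path)
    if meta.get("stream") != "pressure":
        raise FormatError("not a pressure stream", path=path)
    try:
        df = pd.read_csv(path, skiprows=skip)
    except Exception as exc:  # malformed body
        raise FormatError(f"unreadable pressure CSV: {exc}", path=path) from exc
    if df.empty:
        raise InputError(f"empty pressure file {path}")
    sensor_ids = json.loads(meta["sensor_ids"])
    expected = ["time_s"] + sensor_ids
    if list(df.columns) != expected:
        raise FormatError(
            f"column mismatch: expected {len(expected)} columns "
            f"({expected[:3]}...), found {list(df.columns)[:3]}...",
            path=path, row=skip + 1)
    bad = df[df.isna().any(axis=1)]
    if len(bad):
        raise FormatError("non-numeric or missing pressure value",
                          path=path, row=skip + 2 + int(bad.index[0]))
    return PressureFrameSeries(
        dialect=meta["dialect"],
        sampling_rate=float(meta["sampling_rate_hz"]),
        times=df["time_s"].to_numpy(),
        frames=df[sensor_ids].to_numpy(),
        geometry=np.asarray(json.loads(meta["geometry_mm"])),
        sensor_area_cm2=np.asarray(json.loads(meta["sensor_area_cm2"])),
        sensor_ids=sensor_ids,
        meta=json.loads(meta.get("meta", "{}")),
    )


# ------------------------------------------------------------ acceleration

def write_acceleration_csv(accel: AccelerationSeries, path) -> None:
    meta = {
        "stream": "acceleration",
        "sampling_rate_hz": repr(float(accel.sampling_rate)),
        "start": _iso(accel.start),
    }
    df = pd.DataFrame(accel.data, columns=["ax_g", "ay_g", "az_g"])
    df.insert(0, "time_s", accel.times_s())
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        df.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def read_acceleration_csv(path) -> AccelerationSeries:
    path = Path(path)
    meta, skip = _read_meta(path)
    if meta.get("stream") != "acceleration":
        raise FormatError("not an acceleration stream", path=path)
    df = pd.read_csv(path, skiprows=skip)
    if df.empty:
        raise InputError(f"empty acceleration file {path}")
    cols = ["time_s", "ax_g", "ay_g", "az_g"]
    if list(df.columns) != cols:
        raise FormatError(f"expected columns {cols}, found {list(df.columns)}",
                          path=path, row=skip + 1)
    return AccelerationSeries(
        sampling_rate=float(meta["sampling_rate_hz"]),
        start=np.datetime64(pd.Timestamp(meta["start"]).to_datetime64()),
        data=df[["ax_g", "ay_g", "az_g"]].to_numpy(),
    )


# ------------------------------------------------------------- temperature

def write_temperature_csv(log: TemperatureLog, path) -> None:
    df = pd.DataFrame({
        "timestamp_iso": [_iso(t) for t in log.timestamps],
        "temp_c": np.round(log.temps_c, 4),
    })
    with open(path, "w") as fh:
        fh.write(_meta_header({"stream": "temperature"}))
        df.to_csv(fh, index=False, lineterminator="\n")


def read_temperature_csv(path) -> TemperatureLog:
    path = Path(path)
    meta, skip = _read_meta(path)
    if meta.get("stream") != "temperature":
        raise FormatError("not a temperature stream", path=path)
    df = pd.read_csv(path, skiprows=skip)
    if df.empty:
        raise InputError(f"empty temperature file {path}")
    if list(df.columns) != ["timestamp_iso", "temp_c"]:
        raise FormatError("expected columns timestamp_iso,temp_c",
                          path=path, row=skip + 1)
    try:
        ts = pd.to_datetime(df["timestamp_iso"]).to_numpy()
    except (ValueError, TypeError) as exc:
        raise FormatError(f"bad timestamp: {exc}", path=path) from exc
    log = TemperatureLog(timestamps=ts, temps_c=df["temp_c"].to_numpy())
    gaps = log.gaps()
    if gaps:
        # surfaced as metadata; wear extraction handles the splitting
        log.__dict__["gap_intervals"] = gaps
    return log


# ------------------------------------------------------------------ strides

def write_strides_csv(strides: StrideEventSeries, path) -> None:
    df = pd.DataFrame({"timestamp_iso": [_iso(t) for t in strides.timestamps]})
    with open(path, "w") as fh:
        fh.write(_meta_header({"stream": "strides", "source": strides.source}))
        df.to_csv(fh, index=False, lineterminator="\n")


def read_strides_csv(path) -> StrideEventSeries:
    path = Path(path)
    meta, skip = _read_meta(path)
    if meta.get("stream") != "strides":
        raise FormatError("not a stride-event stream", path=path)
    df = pd.read_csv(path, skiprows=skip)
    if list(df.columns) != ["timestamp_iso"]:
        raise FormatError("expected a single timestamp_iso column",
                          path=path, row=skip + 1)
    ts = pd.to_datetime(df["timestamp_iso"]).to_numpy() if len(df) else \
        np.array([], dtype="datetime64[ns]")
    return StrideEventSeries(timestamps=ts,
                             source=meta.get("source", "detected"))


# ------------------------------------------------------------------ thermal

def write_thermal_json(pairs: list[ThermalReadingPair], path) -> None:
    records = []
    for p in pairs:
        for foot, pre, post in (("index", p.index_pre, p.index_post),
                                ("contralateral", p.contra_pre, p.contra_post)):
            records.append({"condition": p.condition.value, "foot": foot,
                            "pre_c": round(float(pre), 6),
                            "post_c": round(float(post), 6)})
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def read_thermal_json(path) -> list[ThermalReadingPair]:
    path = Path(path)
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"bad thermal JSON: {exc}", path=path) from exc
    by_cond: dict[str, dict] = {}
    for i, rec in enumerate(records):
        try:
            by_cond.setdefault(rec["condition"], {})[rec["foot"]] = (
                float(rec["pre_c"]), float(rec["post_c"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"bad thermal record: {exc}",
                              path=path, row=i) from exc
    pairs = []
    for cond, feet in by_cond.items():
        if set(feet) != {"index", "contralateral"}:
            raise FormatError(f"condition {cond!r} missing a foot", path=path)
        pairs.append(ThermalReadingPair(
            condition=Condition(cond),
            index_pre=feet["index"][0], index_post=feet["index"][1],
            contra_pre=feet["contralateral"][0],
            contra_post=feet["contralateral"][1]))
    return pairs


# -------------------------------------------------------------------- misc

def write_wear_json(wear, path) -> None:
    payload = {
        "algorithm": wear.algorithm,
        "params": wear.params,
        "intervals": [[_iso(a), _iso(b)] for a, b in wear.intervals],
        "warnings": list(wear.warnings),
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=float) + "\n")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=1, sort_keys=True, default=float) + "\n")


_READERS = {
    "pressure": read_pressure_csv,
    "acceleration": read_acceleration_csv,
    "temperature": read_temperature_csv,
    "strides": read_strides_csv,
    "thermal": read_thermal_json,
}


def read_stream(path, kind: str):
    """Read a stream file of the given kind into its typed container."""
    if kind not in _READERS:
        raise InputError(f"unknown stream kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    return _READERS[kind](path)
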