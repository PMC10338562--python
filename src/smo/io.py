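"""Reading and writing the tabular record format.

A record table is delimited text (comma-separated, dot decimal, UTF-8,
mandatory header) with one row per second:

    time_s,power_W,hr_bpm,vo2_L_min,phase

``phase`` is optional on input; when absent, phases are inferred from the
power column (leading zero power = baseline, constant low power = warm-up,
rising staircase = ramp, constant power after the ramp = recovery) or taken
from a supplied protocol.  A configurable separator accommodates
semicolon-delimited exports.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .formulas import Subject
from .preprocessing import PhysioSeries
from .protocol import ProtocolSegment, WorkloadProtocol

__all__ = ["write_record", "read_record", "infer_protocol_from_power",
           "read_subjects", "write_json", "load_config"]

REQUIRED_COLUMNS = ("time_s", "power_W", "hr_bpm", "vo2_L_min")
HR_SUSPICIOUS_BPM = 250.0
VO2_SUSPICIOUS_L_MIN = 8.0


class RecordFormatError(ValueError):
    """Malformed record table."""


def write_record(path, hr_series: PhysioSeries, vo2_series: PhysioSeries,
                 protocol: WorkloadProtocol, sep: str = ",") -> None:
    """Write an aligned HR/VO2 record table with the protocol's workload."""
    if hr_series.times.size != vo2_series.times.size or \
            not np.allclose(hr_series.times, vo2_series.times):
        raise ValueError("HR and VO2 series must share one time grid")
    t = hr_series.times
    power = np.array([protocol.power_at(x) for x in t])
    phases = hr_series.phases if hr_series.phases is not None else \
        np.array([protocol.phase_at(x) for x in t], dtype=object)
    pd.DataFrame({
        "time_s": t, "power_W": power, "hr_bpm": hr_series.values,
        "vo2_L_min": vo2_series.values, "phase": phases,
    }).to_csv(path, sep=sep, index=False)


def read_record(path, protocol: Optional[WorkloadProtocol] = None,
                sep: str = ",") -> Tuple[PhysioSeries, PhysioSeries,
                                         WorkloadProtocol]:
    """Read a record table; returns (hr_series, vo2_series, protocol).

    The protocol is inferred from the power column unless supplied.
    Validation failures are raised with row numbers; physiologically
    suspicious values only warn.
    """
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as e:
        raise RecordFormatError(f"{path}: cannot parse ({e})") from e
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RecordFormatError(f"{path}: missing columns {missing}")
    for col in REQUIRED_COLUMNS:
        bad = df.index[df[col].isna()]
        if bad.size:
            raise RecordFormatError(
                f"{path}: missing values in {col!r} at rows {list(bad[:5])}")
    t = df["time_s"].to_numpy(dtype=float)
    nonmono = np.flatnonzero(np.diff(t) <= 0)
    if nonmono.size:
        raise RecordFormatError(
            f"{path}: time_s not strictly increasing at row {nonmono[0] + 1}")
    hr = df["hr_bpm"].to_numpy(dtype=float)
    vo2 = df["vo2_L_min"].to_numpy(dtype=float)
    if np.any(hr > HR_SUSPICIOUS_BPM):
        warnings.warn(f"{path}: HR above {HR_SUSPICIOUS_BPM} bpm — check units",
                      stacklevel=2)
    if np.any(vo2 > VO2_SUSPICIOUS_L_MIN):
        warnings.warn(f"{path}: VO2 above {VO2_SUSPICIOUS_L_MIN} L/min — "
                      "expected L/min, not ml/min", stacklevel=2)
    if protocol is None:
        protocol = infer_protocol_from_power(t, df["power_W"].to_numpy(float))
    if "phase" in df.columns:
        phases = df["phase"].to_numpy(dtype=object)
        bad = [p for p in np.unique(phases)
               if p not in ("baseline", "warmup", "ramp", "recovery")]
        if bad:
            raise RecordFormatError(f"{path}: unknown phase labels {bad}")
    else:
        phases = np.array([protocol.phase_at(x) for x in t], dtype=object)
    hr_series = PhysioSeries(t, hr, "HR", phases)
    vo2_series = PhysioSeries(t, vo2, "VO2", phases)
    return hr_series, vo2_series, protocol


def infer_protocol_from_power(times, power) -> WorkloadProtocol:
    """Segment a sampled power trace into baseline/warmup/ramp/recovery.

    Rules: a leading zero-power stretch is baseline; the following constant
    stretch is warm-up; the rising staircase is the ramp (increment and step
    period taken from the first two steps); the constant stretch after the
    ramp is recovery.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(power, dtype=float)
    if t.size < 3:
        raise RecordFormatError("too few samples to infer a protocol")
    change = np.flatnonzero(np.diff(p) != 0)
    bounds = [0] + [int(i) + 1 for i in change] + [t.size]
    levels = [(t[a], float(p[a]), b - a) for a, b in zip(bounds[:-1], bounds[1:])]

    segs = []
    i = 0
    cursor = 0.0
    # baseline: leading zero power
    if levels and levels[0][1] == 0:
        start, _, n = levels[0]
        dur = float(t[bounds[1]] - cursor) if len(levels) > 1 else float(n)
        segs.append(ProtocolSegment(cursor, dur, "baseline", 0.0))
        cursor += dur
        i = 1
    # warm-up: first nonzero constant level before any increase
    if i < len(levels) - 1 and levels[i + 1][1] > levels[i][1]:
        dur = float(t[bounds[i + 1]] - cursor)
        segs.append(ProtocolSegment(cursor, dur, "warmup", levels[i][1]))
        cursor += dur
        i += 1
    # ramp: maximal run of strictly increasing levels
    ramp_start_idx = i
    while i < len(levels) - 1 and levels[i + 1][1] > levels[i][1]:
        i += 1
    if i > ramp_start_idx:
        first = levels[ramp_start_idx]
        increment = levels[ramp_start_idx + 1][1] - first[1]
        step_period = float(t[bounds[ramp_start_idx + 1]] -
                            t[bounds[ramp_start_idx]])
        ramp_end = float(t[bounds[i + 1]]) if i + 1 < len(bounds) - 1 \
            else float(t[-1] + 1)
        segs.append(ProtocolSegment(cursor, ramp_end - cursor, "ramp",
                                    first[1], increment_W=increment,
                                    step_period_s=step_period))
        cursor = ramp_end
        i += 1
    if not any(s.kind == "ramp" for s in segs):
        raise RecordFormatError("no rising power staircase found")
    # recovery: trailing constant level below the ramp top
    if i <= len(levels) - 1 and cursor < t[-1] + 1:
        segs.append(ProtocolSegment(cursor, float(t[-1] + 1 - cursor),
                                    "recovery", levels[min(i, len(levels) - 1)][1]))
    return WorkloadProtocol(tuple(segs), name="inferred")


def read_subjects(path, sep: str = ",") -> list[Subject]:
    """Read a subject table: id,sex,age,bmi,rhr[,pas][,mass_kg]."""
    df = pd.read_csv(path, sep=sep)
    need = {"id", "sex", "age", "bmi", "rhr"}
    missing = need - set(df.columns)
    if missing:
        raise RecordFormatError(f"{path}: missing subject columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(Subject(
            id=str(row["id"]), sex=str(row["sex"]), age=float(row["age"]),
            bmi=float(row["bmi"]), rhr=float(row["rhr"]),
            pas=float(row["pas"]) if "pas" in df.columns and pd.notna(row.get("pas")) else None,
            mass_kg=float(row["mass_kg"]) if "mass_kg" in df.columns and pd.notna(row.get("mass_kg")) else None,
        ))
    return out


def load_config(path) -> dict:
    """Load a YAML (or JSON) configuration file into a flat dict."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise RecordFormatError(f"{path}: config must be a mapping")
    return cfg


def write_json(path, payload: dict) -> None:
    """Write a JSON report, converting numpy scalars/arrays transparently."""

    def default(o):
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default))
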