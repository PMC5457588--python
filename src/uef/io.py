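"""Plain-text file formats: motion traces and cohort tables.

Trace files are comma-separated time series, one file per 20-s trial, with
the sampling rate declared in a commented header line::

    # sampling_rate_hz: 100.0
    time_s,forearm_velocity_dps,upperarm_velocity_dps
    0.000000,12.345678,-0.123456
    ...

Cohort files are comma-separated tables keyed by ``id``; the Fried category
is stored as a human-editable string (trimmed and lower-cased on read) and
ordered internally.  UEF parameter columns may be absent before extraction.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import FRIED_CATEGORIES
from .trace import MotionTrace

TRACE_COLUMNS = ("time_s", "forearm_velocity_dps", "upperarm_velocity_dps")

#: Column dictionary for the cohort table.
COHORT_COLUMNS = {
    "id": "subject identifier, unique",
    "fried_group": "Fried category: non-frail | pre-frail | frail",
    "age_years": "age, years",
    "sex": "female | male",
    "height_cm": "stature, cm",
    "weight_kg": "body mass, kg",
    "bmi_kgm2": "body mass index, kg/m^2",
    "mmse": "mini-mental state examination, 0-30",
    "speed": "mean elbow angular-velocity range, deg/s",
    "flexibility": "mean elbow flexion range, deg",
    "power": "mean acceleration-range x velocity-range product, deg^2/s^3",
    "rise_time": "mean time to peak angular velocity, s",
    "moment": "mean peak elbow moment, Nm",
    "speed_variability": "CV of per-cycle velocity ranges, %",
    "speed_reduction": "percent change, last vs first 5 s (negative = slowing)",
    "flexion_number": "flexion/extension cycles in 20 s",
}

REQUIRED_COHORT_COLUMNS = ("id", "fried_group")


def write_trace(trace: MotionTrace, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "forearm_velocity_dps": trace.forearm_velocity,
            "upperarm_velocity_dps": trace.upperarm_velocity,
        }
    )
    with path.open("w") as fh:
        fh.write(f"# sampling_rate_hz: {trace.sampling_rate!r}\n")
        if trace.subject_id is not None:
            fh.write(f"# subject_id: {trace.subject_id}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_trace(path) -> MotionTrace:
    """Read a trace file; validates the header, columns and time base."""
    path = Path(path)
    rate = None
    subject_id = None
    body = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                key = key.strip()
                if key == "sampling_rate_hz":
                    rate = float(val)
                elif key == "subject_id":
                    subject_id = val.strip()
            else:
                body.append(line)
    if rate is None:
        raise ValueError(f"{path}: malformed header, no '# sampling_rate_hz:' line")
    df = pd.read_csv(_io.StringIO("".join(body)))
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time_s must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / rate)) > 0.01 / rate:
            raise ValueError(
                f"{path}: non-uniform time steps (declared rate {rate} Hz)"
            )
    return MotionTrace(
        sampling_rate=rate,
        time=t,
        forearm_velocity=df["forearm_velocity_dps"].to_numpy(dtype=float),
        upperarm_velocity=df["upperarm_velocity_dps"].to_numpy(dtype=float),
        subject_id=subject_id,
    )


def _parse_category(value: str) -> str:
    cleaned = str(value).strip().lower()
    aliases = {c: c for c in FRIED_CATEGORIES}
    aliases.update({"nonfrail": "non-frail", "non frail": "non-frail",
                    "prefrail": "pre-frail", "pre frail": "pre-frail"})
    if cleaned not in aliases:
        raise ValueError(f"unknown Fried category {value!r}")
    return aliases[cleaned]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(Path(path), index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table; Fried categories become an ordered categorical.

    Missing UEF parameter columns are permitted (pre-extraction tables).
    Raises on unknown category strings or duplicated ids.
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicated id(s): {sorted(set(map(str, dup)))}")
    df["fried_group"] = pd.Categorical(
        [_parse_category(v) for v in df["fried_group"]],
        categories=list(FRIED_CATEGORIES),
        ordered=True,
    )
    return df
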