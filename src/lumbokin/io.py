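"""Trial file reading/writing, stream validation findings, and resampling.

Trial file format (plain text): the first line is a JSON header object
``{"participant_id", "test_id", "pace", "sex", "age", "fs"}``; every
following line is one sample of one sensor, comma-delimited::

    sensor_id,t,qw,qx,qy,qz,gx,gy,gz,ax,ay,az

Floats are serialized with ``%.17g`` (full round-trip precision), so
write -> read is exact and write -> read -> write is byte-identical.
"""
from __future__ import annotations

import io as _io
import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

from .errors import ParseError, StreamError
from .types import (FS_NOMINAL, Pace, QUAT_NORM_TOL, Sensor, SensorStream, Sex,
                    TestId, TrialRecording)

_COLUMNS = ["sensor_id", "t", "qw", "qx", "qy", "qz",
            "gx", "gy", "gz", "ax", "ay", "az"]


def write_trial(rec: TrialRecording, path: str | os.PathLike) -> None:
    """Serialize ``rec`` to the trial text format at ``path``.

    Sensors are written in fixed enum order so output is deterministic.
    """
    header = {
        "participant_id": rec.participant_id,
        "test_id": rec.test_id.value,
        "pace": rec.pace.value,
        "sex": rec.sex.value,
        "age": rec.age,
        "fs": rec.fs,
    }
    buf = _io.StringIO()
    buf.write(json.dumps(header, sort_keys=True) + "\n")
    for sensor in Sensor:
        if sensor not in rec.streams:
            continue
        s = rec.streams[sensor]
        block = np.column_stack([s.t, s.quat, s.gyro, s.accel])
        for row in block:
            buf.write(sensor.value + "," + ",".join("%.17g" % v for v in row) + "\n")
    try:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    except OSError as exc:
        raise OSError(f"cannot write trial file {path!r}: {exc}") from exc


def read_trial(path: str | os.PathLike) -> TrialRecording:
    """Parse and validate a trial file.

    Raises
    ------
    ParseError
        Malformed header or rows.
    StreamError
        Stream invariant violations (via :meth:`SensorStream.validate`),
        e.g. a quaternion norm off by more than ``QUAT_NORM_TOL``.
    """
    with open(path) as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
            test_id = TestId(header["test_id"])
            pace = Pace(header["pace"])
            sex = Sex(header.get("sex", "unknown"))
            meta = (str(header["participant_id"]), test_id, pace, sex,
                    float(header.get("age", math.nan)),
                    float(header.get("fs", FS_NOMINAL)))
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise ParseError(f"bad trial header in {path!r}: {exc}") from exc
        try:
            df = pd.read_csv(fh, names=_COLUMNS, header=None,
                             float_precision="round_trip")
        except Exception as exc:  # noqa: BLE001 - pandas raises many types here
            raise ParseError(f"bad trial rows in {path!r}: {exc}") from exc
    if df.empty:
        raise ParseError(f"trial file {path!r} has no sensor rows")
    if df[_COLUMNS[1:]].isna().to_numpy().any() or df["sensor_id"].isna().any():
        raise ParseError(f"trial file {path!r} has missing fields")

    pid, test_id, pace, sex, age, fs = meta
    streams: dict[Sensor, SensorStream] = {}
    for sensor_name, grp in df.groupby("sensor_id", sort=False):
        try:
            sensor = Sensor(sensor_name)
        except ValueError as exc:
            raise ParseError(f"unknown sensor id {sensor_name!r} in {path!r}") from exc
        arr = grp[_COLUMNS[1:]].to_numpy(dtype=float)
        streams[sensor] = SensorStream(
            sensor, arr[:, 0], arr[:, 1:5], arr[:, 5:8], arr[:, 8:11]
        ).validate()
    return TrialRecording(pid, test_id, pace, streams, sex, age, fs)


# ------------------------------------------------------------- validation


@dataclass
class Finding:
    """One data-quality finding from :func:`validate_stream`."""

    kind: str       # "norm_drift" | "gap" | "timing" | "nan"
    index: int      # first sample involved
    detail: str

    def __repr__(self) -> str:  # compact in logs
        return f"Finding({self.kind}@{self.index}: {self.detail})"


def validate_stream(s: SensorStream,
                    fs_nominal: float = FS_NOMINAL,
                    norm_tol: float = 1e-3,
                    interval_tol: float = 0.2,
                    gap_factor: float = 2.0) -> list[Finding]:
    """Enumerate data-quality problems; an empty list means a clean stream.

    Checks: quaternion-norm drift beyond ``norm_tol``; sampling intervals
    deviating more than ``interval_tol`` (fraction) from the nominal 16 ms;
    gaps (interval > ``gap_factor`` x nominal); NaNs in any channel.
    """
    findings: list[Finding] = []
    for name, arr in (("t", s.t), ("quat", s.quat), ("gyro", s.gyro),
                      ("accel", s.accel)):
        nan_rows = np.isnan(arr).reshape(len(s), -1).any(axis=1)
        if nan_rows.any():
            i = int(np.argmax(nan_rows))
            findings.append(Finding("nan", i, f"NaN in {name}"))
    norms = np.linalg.norm(s.quat, axis=1)
    drift = np.abs(norms - 1.0) > norm_tol
    if drift.any():
        i = int(np.argmax(drift))
        findings.append(Finding("norm_drift", i, f"|q|={norms[i]:.4f}"))
    if len(s) >= 2:
        dt = np.diff(s.t)
        nominal = 1.0 / fs_nominal
        gaps = dt > gap_factor * nominal
        for i in np.flatnonzero(gaps):
            findings.append(Finding("gap", int(i), f"dt={dt[i] * 1e3:.1f} ms"))
        off = (np.abs(dt - nominal) > interval_tol * nominal) & ~gaps
        if off.any():
            i = int(np.argmax(off))
            findings.append(Finding("timing", i, f"dt={dt[i] * 1e3:.1f} ms"))
    return findings


# ------------------------------------------------------------- resampling


def resample_uniform(s: SensorStream, fs: float) -> SensorStream:
    """Resample onto a uniform grid at ``fs`` Hz spanning ``[t0, tN]``.

    Quaternions are interpolated by slerp between bracketing samples,
    gyro/accel linearly.  Idempotent on already-uniform input.
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if len(s) < 2:
        raise StreamError("resampling needs at least 2 samples")
    t0, tn = float(s.t[0]), float(s.t[-1])
    n = int(np.floor((tn - t0) * fs + 1e-9)) + 1
    t_new = t0 + np.arange(n) / fs
    t_new = np.clip(t_new, t0, tn)  # guard fp overshoot at the end

    q = s.quat / np.linalg.norm(s.quat, axis=1, keepdims=True)
    # enforce sign continuity so slerp takes the short way
    flips = np.cumsum(np.sum(q[1:] * q[:-1], axis=1) < 0) % 2
    q[1:][flips == 1] *= -1.0
    slerp = Slerp(s.t, Rotation.from_quat(q[:, [1, 2, 3, 0]]))
    q_new = slerp(t_new).as_quat()[:, [3, 0, 1, 2]]

    gyro_new = np.column_stack([np.interp(t_new, s.t, s.gyro[:, i]) for i in range(3)])
    accel_new = np.column_stack([np.interp(t_new, s.t, s.accel[:, i]) for i in range(3)])
    return SensorStream(s.sensor_id, t_new, q_new, gyro_new, accel_new).validate()
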