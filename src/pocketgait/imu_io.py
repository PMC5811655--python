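"""Data model and readers/writers for pocket-IMU recordings and result tables.

A recording is a time-stamped stream of device-frame accelerometer and
gyroscope samples together with the device attitude quaternion for each
sample (scalar-first ``w, x, y, z``, describing the rotation that carries a
device-frame vector into the earth frame). Two on-disk dialects are
supported:

* ``wide_csv`` — one row per sample with header
  ``t,ax,ay,az,gx,gy,gz,qw,qx,qy,qz``;
* ``json_log`` — JSON-lines, one object per sample with the same keys
  (phone-export style).

Times are seconds, accelerations m/s^2 (or g with a config flag), angular
velocities rad/s.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

G_PER_MS2 = 9.80665

RECORDING_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz", "qw", "qx", "qy", "qz")

#: Maximum tolerated quaternion norm deviation after load-time renormalization.
QUAT_NORM_TOL = 1e-6


class Condition(str, Enum):
    NORMAL = "normal"
    DUAL_TASK = "dual_task"


class Setting(str, Enum):
    LAB = "lab"
    HOME = "home"


class PocketTightness(str, Enum):
    TIGHT = "tight"
    MEDIUM = "medium"
    LOOSE = "loose"
    UNKNOWN = "unknown"


@dataclass
class TrialMeta:
    """Descriptive metadata for one walking trial."""

    condition: Condition = Condition.NORMAL
    setting: Setting = Setting.LAB
    pocket_tightness: PocketTightness = PocketTightness.UNKNOWN
    duration_s: float = 45.0
    participant_id: str = ""
    visit_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.setting = Setting(self.setting)
        self.pocket_tightness = PocketTightness(self.pocket_tightness)
        if self.duration_s <= 0:
            raise DataError("duration_s must be positive")


@dataclass
class IMURecording:
    """A validated 6-axis recording with per-sample attitude quaternions.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    accel : ndarray, shape (n, 3)
        Device-frame acceleration, m/s^2.
    gyro : ndarray, shape (n, 3)
        Device-frame angular velocity, rad/s.
    quat : ndarray, shape (n, 4)
        Unit attitude quaternions, scalar-first (w, x, y, z).
    fs_nominal : float
        Nominal sampling rate, Hz.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    quat: np.ndarray
    fs_nominal: float = 100.0
    meta: TrialMeta | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        n = len(self.t)
        for name, arr, ncol in (("accel", self.accel, 3), ("gyro", self.gyro, 3), ("quat", self.quat, 4)):
            if arr.shape != (n, ncol):
                raise DataError(
                    f"array length mismatch: {name} has shape {arr.shape}, expected ({n}, {ncol})"
                )
        dt = np.diff(self.t)
        if n > 1 and np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise DataError(f"time vector not strictly increasing at index {idx + 1}")
        norms = np.linalg.norm(self.quat, axis=1)
        if np.any(norms == 0):
            idx = int(np.argmax(norms == 0))
            raise DataError(f"zero-norm quaternion at sample {idx}")
        self.quat = self.quat / norms[:, None]
        if n > 1:
            med_dt = float(np.median(dt))
            nominal_dt = 1.0 / self.fs_nominal
            if not 0.8 * nominal_dt <= med_dt <= 1.2 * nominal_dt:
                raise DataError(
                    f"median sampling interval {med_dt:.4f}s deviates >20% from "
                    f"nominal {nominal_dt:.4f}s"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def fs_observed(self) -> float:
        """Sampling rate implied by the median inter-sample interval."""
        return 1.0 / float(np.median(np.diff(self.t)))


def _validate_columns(present: set[str]) -> None:
    for col in RECORDING_COLUMNS:
        if col not in present:
            raise FormatError(f"missing column {col}")


def _resample_uniform(rec: IMURecording) -> IMURecording:
    """Linearly interpolate all channels onto a uniform fs_nominal grid."""
    t_new = np.arange(rec.t[0], rec.t[-1] + 0.5 / rec.fs_nominal, 1.0 / rec.fs_nominal)

    def interp_cols(arr: np.ndarray) -> np.ndarray:
        return np.column_stack([np.interp(t_new, rec.t, arr[:, j]) for j in range(arr.shape[1])])

    quat = interp_cols(rec.quat)  # renormalized by the constructor
    return IMURecording(
        t=t_new,
        accel=interp_cols(rec.accel),
        gyro=interp_cols(rec.gyro),
        quat=quat,
        fs_nominal=rec.fs_nominal,
        meta=rec.meta,
    )


def _build_recording(df: pd.DataFrame, fs_nominal: float, accel_unit: str,
                     meta: TrialMeta | None) -> IMURecording:
    t = df["t"].to_numpy(dtype=float)
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if accel_unit == "g":
        accel = accel * G_PER_MS2
    rec = IMURecording(
        t=t,
        accel=accel,
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        quat=df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float),
        fs_nominal=fs_nominal,
        meta=meta,
    )
    dt = np.diff(rec.t)
    gap = 3.0 / fs_nominal
    n_gaps = int(np.sum(dt > gap))
    if n_gaps:
        logger.warning("%d gaps longer than 3 nominal sampling intervals", n_gaps)
    med_dt = float(np.median(dt)) if len(dt) else 1.0 / fs_nominal
    if abs(med_dt - 1.0 / fs_nominal) > 0.01 / fs_nominal:
        logger.info("irregular sampling (median dt %.5fs); resampling to %.0f Hz",
                    med_dt, fs_nominal)
        rec = _resample_uniform(rec)
    return rec


def read_recording(path: str | Path, dialect: str = "wide_csv", *,
                   fs_nominal: float = 100.0, accel_unit: str = "m/s^2",
                   meta: TrialMeta | None = None) -> IMURecording:
    """Read a recording from disk and validate it.

    Parameters
    ----------
    path : path
        Input file.
    dialect : {"wide_csv", "json_log"}
        On-disk layout.
    fs_nominal : float
        Nominal sampling rate in Hz (default 100).
    accel_unit : {"m/s^2", "g"}
        Unit of the accelerometer columns; ``g`` values are converted.
    meta : TrialMeta, optional
        Trial metadata to attach.

    Raises
    ------
    FormatError
        Missing column/key or unknown dialect.
    DataError
        Non-monotone time vector, zero-norm quaternion, length mismatch,
        or sampling rate off-nominal by more than 20%.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "wide_csv":
        df = pd.read_csv(path)
        _validate_columns(set(df.columns))
    elif dialect == "json_log":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise FormatError(f"invalid JSON on line {lineno}: {exc}") from exc
        if not rows:
            raise FormatError("empty JSON log")
        _validate_columns(set(rows[0]))
        df = pd.DataFrame(rows)
        _validate_columns(set(df.columns))
        if df[list(RECORDING_COLUMNS)].isna().any().any():
            raise FormatError("missing keys in some JSON log records")
    else:
        raise FormatError(f"unknown dialect: {dialect}")
    return _build_recording(df, fs_nominal, accel_unit, meta)


def write_recording(rec: IMURecording, path: str | Path, dialect: str = "wide_csv") -> None:
    """Write a recording in one of the supported dialects."""
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.accel, rec.gyro, rec.quat]),
        columns=list(RECORDING_COLUMNS),
    )
    if dialect == "wide_csv":
        df.to_csv(path, index=False)
    elif dialect == "json_log":
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(json.dumps(dict(zip(RECORDING_COLUMNS, row))) + "\n")
    else:
        raise FormatError(f"unknown dialect: {dialect}")


STRIDE_TABLE_COLUMNS = ("stride_index", "hs_time_s", "stride_time_s", "excluded_for_turn")


def write_stride_table(strides: pd.DataFrame, path: str | Path) -> None:
    """Write a per-stride table (columns ``stride_index, hs_time_s,
    stride_time_s, excluded_for_turn``) as CSV; an empty frame yields a
    header-only file."""
    missing = [c for c in STRIDE_TABLE_COLUMNS if c not in strides.columns]
    if missing:
        raise FormatError(f"stride table missing columns: {missing}")
    strides.loc[:, list(STRIDE_TABLE_COLUMNS)].to_csv(path, index=False)


def read_stride_table(path: str | Path) -> pd.DataFrame:
    """Read a stride table written by :func:`write_stride_table`."""
    df = pd.read_csv(path)
    missing = [c for c in STRIDE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"stride table missing columns: {missing}")
    df["stride_index"] = df["stride_index"].astype(int)
    df["excluded_for_turn"] = df["excluded_for_turn"].astype(bool)
    return df
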