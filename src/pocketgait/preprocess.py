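"""Earth-frame rotation and zero-phase filtering.

The phone reports its attitude as a unit quaternion per sample. Rotating
each device-frame accelerometer and gyroscope vector by that quaternion
expresses it in an earth-fixed frame whose z-axis runs from the earth's
centre through the device, i.e. vertically. Gait events are read from the
filtered earth-frame vertical acceleration; turns from the earth-frame
vertical angular velocity.

Filtering is a low-pass Butterworth applied forward-backward (zero phase),
because event timing is taken from filtered extrema and any phase lag would
bias stride times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .config import PipelineConfig
from .errors import DataError, ParameterError
from .imu_io import IMURecording


@dataclass
class EarthFrameSeries:
    """Earth-frame vertical channels of one trial.

    ``az`` is vertical acceleration (m/s^2, gravity offset retained),
    ``wz`` vertical-axis angular velocity (rad/s); ``_raw`` are the rotated
    channels, ``_filt`` the zero-phase low-passed versions.
    """

    t: np.ndarray
    az_raw: np.ndarray
    az_filt: np.ndarray | None
    wz_raw: np.ndarray
    wz_filt: np.ndarray | None
    fs: float

    def __len__(self) -> int:
        return len(self.t)


def quat_rotate(quat: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Actively rotate device-frame vectors into the earth frame.

    Parameters
    ----------
    quat : ndarray, shape (n, 4) or (4,)
        Scalar-first unit quaternions (w, x, y, z).
    vec : ndarray, shape (n, 3) or (3,)
        Device-frame vectors.
    """
    quat = np.asarray(quat, dtype=float)
    vec = np.asarray(vec, dtype=float)
    norms = np.linalg.norm(np.atleast_2d(quat), axis=1)
    if np.any(norms == 0):
        idx = int(np.argmax(norms == 0))
        raise DataError(f"zero-norm quaternion at sample {idx}")
    return Rotation.from_quat(quat, scalar_first=True).apply(vec)


def rotate_to_earth(rec: IMURecording) -> EarthFrameSeries:
    """Rotate a recording into the earth frame and extract the vertical channels.

    Each sample's acceleration and angular-velocity vector is rotated by
    that sample's attitude quaternion; the z-components form ``az_raw`` and
    ``wz_raw``. Filtered channels are left unset (see
    :func:`preprocess_recording`).
    """
    accel_earth = quat_rotate(rec.quat, rec.accel)
    gyro_earth = quat_rotate(rec.quat, rec.gyro)
    return EarthFrameSeries(
        t=rec.t,
        az_raw=accel_earth[:, 2],
        az_filt=None,
        wz_raw=gyro_earth[:, 2],
        wz_filt=None,
        fs=rec.fs_nominal,
    )


def filter_channel(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter.

    The filter is applied forward then backward (``filtfilt``), so the
    effective magnitude response is the squared single-pass Butterworth
    response ``|H(f)|^2 = 1 / (1 + (f/fc)^(2*order))`` and the phase
    response is zero: a symmetric pulse keeps its peak sample.

    Raises
    ------
    ParameterError
        If ``cutoff >= fs/2`` or the series is too short for the filter order.
    """
    x = np.asarray(x, dtype=float)
    if cutoff >= fs / 2:
        raise ParameterError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    if len(x) <= 3 * order:
        raise ParameterError(f"series of length {len(x)} too short for order {order}")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    return filtfilt(b, a, x)


def preprocess_recording(rec: IMURecording, config: PipelineConfig | None = None) -> EarthFrameSeries:
    """Rotate to the earth frame and filter the vertical channels.

    ``wz`` is filtered with the same low-pass as ``az`` unless
    ``config.turns_filter_wz`` is false, in which case ``wz_filt`` is the
    raw rotated channel.
    """
    config = config or PipelineConfig()
    series = rotate_to_earth(rec)
    az = filter_channel(series.az_raw, series.fs, config.filter_cutoff_hz, config.filter_order)
    if config.subtract_mean_accel:
        az = az - az.mean()
    series.az_filt = az
    if config.turns_filter_wz:
        series.wz_filt = filter_channel(series.wz_raw, series.fs,
                                        config.filter_cutoff_hz, config.filter_order)
    else:
        series.wz_filt = series.wz_raw.copy()
    return series
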