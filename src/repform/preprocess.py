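"""Signal conditioning and the 18-channel signal set.

From each 9-channel recording the pipeline derives nine additional
signals: the four components of the orientation quaternion estimated by
the Madgwick gradient-descent MARG filter, the pitch/roll/yaw inclination
angles (sagittal, frontal and transverse planes, radians), and the vector
magnitudes of the accelerometer and gyroscope triads.  Accelerometer and
gyroscope channels are zero-phase low-pass filtered (Butterworth, order 8,
20 Hz cut-off) beforehand; the magnetometer is passed through unfiltered
since its error budget is dominated by field disturbance rather than
wideband sensor noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .streams import ImuStream

logger = logging.getLogger(__name__)

__all__ = [
    "SignalSet",
    "SIGNAL_NAMES",
    "lowpass_filter",
    "MadgwickFilter",
    "estimate_orientation",
    "quaternion_to_euler",
    "euler_to_quaternion",
    "vector_magnitude",
    "build_signal_set",
]

#: the fixed 18-name channel list, in feature-vector order
SIGNAL_NAMES = (
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "mag_x", "mag_y", "mag_z",
    "quat_w", "quat_x", "quat_y", "quat_z",
    "pitch", "roll", "yaw",
    "acc_mag", "gyro_mag",
)

DEG2RAD = np.pi / 180.0


@dataclass
class SignalSet:
    """The 18 processed channels of one recording, sampled at ``fs`` Hz."""

    channels: dict[str, np.ndarray]
    fs: float
    session_id: str = ""
    exercise: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.channels.keys()) != SIGNAL_NAMES:
            # accept any ordering / detect wrong names, then canonicalize
            missing = set(SIGNAL_NAMES) - set(self.channels)
            extra = set(self.channels) - set(SIGNAL_NAMES)
            if missing or extra:
                raise ValueError(
                    f"signal set must contain exactly the 18 channels; "
                    f"missing={sorted(missing)} extra={sorted(extra)}"
                )
            self.channels = {name: self.channels[name] for name in SIGNAL_NAMES}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
        q = np.column_stack([self.channels[c] for c in ("quat_w", "quat_x", "quat_y", "quat_z")])
        norms = np.linalg.norm(q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternion channels are not unit-norm to 1e-6")

    def __len__(self) -> int:
        return len(self.channels["acc_x"])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def slice(self, start: int, stop: int) -> "SignalSet":
        """All 18 channels cut identically to ``[start, stop)``."""
        if not (0 <= start < stop <= len(self)):
            raise IndexError(f"invalid slice [{start}, {stop}) for length {len(self)}")
        return SignalSet(
            channels={k: v[start:stop] for k, v in self.channels.items()},
            fs=self.fs,
            session_id=self.session_id,
            exercise=self.exercise,
            meta=dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.channels)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, fs: float, session_id: str = "", exercise: str = ""
    ) -> "SignalSet":
        return cls(
            channels={name: df[name].to_numpy(dtype=float) for name in SIGNAL_NAMES},
            fs=fs,
            session_id=session_id,
            exercise=exercise,
        )


def lowpass_filter(
    signal: np.ndarray, fs: float, fc: float = 20.0, order: int = 8
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    A single filter of the given order is designed as second-order
    sections and applied forward and backward (``sosfiltfilt``), doubling
    the magnitude attenuation and cancelling phase lag, so repetition
    boundaries detected downstream are not shifted in time.  DC gain is
    exactly 1.
    """
    signal = np.asarray(signal, dtype=float)
    if not 0 < fc < fs / 2:
        raise ValueError(f"cut-off {fc} Hz must lie in (0, {fs / 2}) Hz")
    if len(signal) <= 3 * order:
        raise ValueError(f"signal of length {len(signal)} too short for order {order}")
    sos = butter(order, fc, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, signal)


# ---------------------------------------------------------------------------
# Orientation estimation (Madgwick gradient-descent MARG filter)
# ---------------------------------------------------------------------------


class MadgwickFilter:
    """Gradient-descent orientation filter fusing gyro, accelerometer and
    magnetometer.

    The state is the unit quaternion ``q = (w, x, y, z)`` rotating sensor-
    frame vectors into the earth frame (``v_e = q (0, v_s) q*``).  Each
    step integrates the gyroscope rate and corrects it by the normalized
    gradient of the joint gravity + magnetic-field objective, scaled by
    the gain ``beta`` (rad/s).  Samples with a zero-norm accelerometer or
    magnetometer reading propagate by gyro integration alone.

    ``beta`` trades convergence speed against noise rejection; 0.1 rad/s
    is a common compromise for slow, deliberate limb movement.
    """

    def __init__(self, fs: float, beta: float = 0.1):
        if fs <= 0:
            raise ValueError("fs must be positive")
        if beta < 0:
            raise ValueError("beta must be non-negative")
        self.fs = float(fs)
        self.beta = float(beta)

    # The update below follows the published MARG formulation with the
    # earth magnetic reference collapsed to (b1, 0, b3).
    def run(
        self,
        acc: np.ndarray,
        gyro: np.ndarray,
        mag: np.ndarray,
        q0: np.ndarray | None = None,
    ) -> np.ndarray:
        """Filter whole arrays; ``gyro`` in rad/s.  Returns (n, 4) unit
        quaternions (w, x, y, z), one per sample."""
        acc = np.asarray(acc, dtype=float)
        gyro = np.asarray(gyro, dtype=float)
        mag = np.asarray(mag, dtype=float)
        if not (acc.shape == gyro.shape == mag.shape) or acc.ndim != 2 or acc.shape[1] != 3:
            raise ValueError("acc, gyro, mag must share shape (n, 3)")
        n = acc.shape[0]
        if q0 is None:
            q0 = orientation_from_acc_mag(acc[0], mag[0])
        w, x, y, z = (float(v) for v in q0)
        dt = 1.0 / self.fs
        beta = self.beta
        out = np.empty((n, 4), dtype=float)
        for k in range(n):
            gx, gy, gz = gyro[k]
            # rate of change from gyro: 0.5 * q ⊗ (0, ω)
            qdw = 0.5 * (-x * gx - y * gy - z * gz)
            qdx = 0.5 * (w * gx + y * gz - z * gy)
            qdy = 0.5 * (w * gy - x * gz + z * gx)
            qdz = 0.5 * (w * gz + x * gy - y * gx)

            ax, ay, az = acc[k]
            mx, my, mz = mag[k]
            a_norm = (ax * ax + ay * ay + az * az) ** 0.5
            m_norm = (mx * mx + my * my + mz * mz) ** 0.5
            if beta > 0.0 and a_norm > 0.0 and m_norm > 0.0:
                ax, ay, az = ax / a_norm, ay / a_norm, az / a_norm
                mx, my, mz = mx / m_norm, my / m_norm, mz / m_norm

                # earth-frame flux h = q ⊗ (0, m) ⊗ q*, reference (b1, 0, b3)
                hx = (
                    mx * (1.0 - 2.0 * (y * y + z * z))
                    + my * 2.0 * (x * y - w * z)
                    + mz * 2.0 * (x * z + w * y)
                )
                hy = (
                    mx * 2.0 * (x * y + w * z)
                    + my * (1.0 - 2.0 * (x * x + z * z))
                    + mz * 2.0 * (y * z - w * x)
                )
                hz = (
                    mx * 2.0 * (x * z - w * y)
                    + my * 2.0 * (y * z + w * x)
                    + mz * (1.0 - 2.0 * (x * x + y * y))
                )
                b1 = (hx * hx + hy * hy) ** 0.5
                b3 = hz

                # objective: predicted gravity / flux minus measurements
                f1 = 2.0 * (x * z - w * y) - ax
                f2 = 2.0 * (w * x + y * z) - ay
                f3 = 1.0 - 2.0 * (x * x + y * y) - az
                f4 = 2.0 * b1 * (0.5 - y * y - z * z) + 2.0 * b3 * (x * z - w * y) - mx
                f5 = 2.0 * b1 * (x * y - w * z) + 2.0 * b3 * (w * x + y * z) - my
                f6 = 2.0 * b1 * (w * y + x * z) + 2.0 * b3 * (0.5 - x * x - y * y) - mz

                # gradient = J^T f (Jacobian of the objective wrt q)
                gw = (
                    -2.0 * y * f1
                    + 2.0 * x * f2
                    - 2.0 * b3 * y * f4
                    + (-2.0 * b1 * z + 2.0 * b3 * x) * f5
                    + 2.0 * b1 * y * f6
                )
                gqx = (
                    2.0 * z * f1
                    + 2.0 * w * f2
                    - 4.0 * x * f3
                    + 2.0 * b3 * z * f4
                    + (2.0 * b1 * y + 2.0 * b3 * w) * f5
                    + (2.0 * b1 * z - 4.0 * b3 * x) * f6
                )
                gqy = (
                    -2.0 * w * f1
                    + 2.0 * z * f2
                    - 4.0 * y * f3
                    + (-4.0 * b1 * y - 2.0 * b3 * w) * f4
                    + (2.0 * b1 * x + 2.0 * b3 * z) * f5
                    + (2.0 * b1 * w - 4.0 * b3 * y) * f6
                )
                gqz = (
                    2.0 * x * f1
                    + 2.0 * y * f2
                    + (-4.0 * b1 * z + 2.0 * b3 * x) * f4
                    + (-2.0 * b1 * w + 2.0 * b3 * y) * f5
                    + 2.0 * b1 * x * f6
                )
                g_norm = (gw * gw + gqx * gqx + gqy * gqy + gqz * gqz) ** 0.5
                # a numerically zero gradient means the state already matches
                # the measurements; normalizing it would inject a beta-sized
                # random-walk step, so skip the correction instead
                if g_norm > 1e-9:
                    qdw -= beta * gw / g_norm
                    qdx -= beta * gqx / g_norm
                    qdy -= beta * gqy / g_norm
                    qdz -= beta * gqz / g_norm

            w += qdw * dt
            x += qdx * dt
            y += qdy * dt
            z += qdz * dt
            inv = 1.0 / (w * w + x * x + y * y + z * z) ** 0.5
            w, x, y, z = w * inv, x * inv, y * inv, z * inv
            out[k, 0], out[k, 1], out[k, 2], out[k, 3] = w, x, y, z
        return out


def orientation_from_acc_mag(acc: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Algebraic orientation from one accelerometer + magnetometer sample.

    Tilt (pitch, roll) from the gravity direction, heading from the
    tilt-compensated magnetometer; returns the quaternion of the
    aerospace Z-Y-X Euler triple.  Falls back to identity when either
    vector has zero norm.
    """
    acc = np.asarray(acc, dtype=float)
    mag = np.asarray(mag, dtype=float)
    if np.linalg.norm(acc) == 0 or np.linalg.norm(mag) == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    ax, ay, az = acc / np.linalg.norm(acc)
    pitch = np.arcsin(np.clip(-ax, -1.0, 1.0))
    roll = np.arctan2(ay, az)
    mx, my, mz = mag / np.linalg.norm(mag)
    # rotate the magnetometer reading back through roll then pitch
    mx2 = mx * np.cos(pitch) + my * np.sin(pitch) * np.sin(roll) + mz * np.sin(pitch) * np.cos(roll)
    my2 = my * np.cos(roll) - mz * np.sin(roll)
    yaw = np.arctan2(-my2, mx2)
    return euler_to_quaternion(pitch, roll, yaw)


def estimate_orientation(
    acc: np.ndarray,
    gyro: np.ndarray,
    mag: np.ndarray,
    fs: float,
    beta: float = 0.1,
    q0: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample unit quaternions (w, x, y, z) from MARG data.

    ``gyro`` must be supplied in rad/s.  The state is initialized from
    the first accelerometer/magnetometer sample's algebraic orientation
    unless ``q0`` is given.
    """
    return MadgwickFilter(fs=fs, beta=beta).run(acc, gyro, mag, q0=q0)


def quaternion_to_euler(q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit quaternions -> (pitch, roll, yaw) in radians, aerospace Z-Y-X.

    Pitch is the sagittal-plane inclination in [-pi/2, pi/2]; roll
    (frontal) and yaw (transverse) lie in (-pi, pi].  Within 1e-6 rad of
    gimbal lock (|pitch| = pi/2) roll is set to zero and yaw absorbs the
    full remaining rotation; such samples are reported via a warning log.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    sin_pitch = np.clip(2.0 * (w * y - x * z), -1.0, 1.0)
    pitch = np.arcsin(sin_pitch)
    roll = np.arctan2(2.0 * (w * x + y * z), 1.0 - 2.0 * (x * x + y * y))
    yaw = np.arctan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z))
    locked = np.abs(np.abs(pitch) - np.pi / 2) < 1e-6
    if np.any(locked):
        logger.warning(
            "gimbal lock at %d sample(s); yaw set by the degenerate-case formula",
            int(np.sum(locked)),
        )
        # at |pitch| = pi/2 only (yaw -/+ roll) is observable: put it all in yaw
        sign = np.sign(sin_pitch[locked])
        roll = roll.copy()
        yaw = yaw.copy()
        roll[locked] = 0.0
        yaw[locked] = -sign * 2.0 * np.arctan2(x[locked], w[locked])
    return pitch, roll, yaw


def euler_to_quaternion(pitch, roll, yaw) -> np.ndarray:
    """Aerospace Z-Y-X Euler angles (radians) -> unit quaternion(s)."""
    pitch, roll, yaw = (np.asarray(v, dtype=float) for v in (pitch, roll, yaw))
    cy, sy = np.cos(yaw / 2), np.sin(yaw / 2)
    cp, sp = np.cos(pitch / 2), np.sin(pitch / 2)
    cr, sr = np.cos(roll / 2), np.sin(roll / 2)
    w = cy * cp * cr + sy * sp * sr
    x = cy * cp * sr - sy * sp * cr
    y = cy * sp * cr + sy * cp * sr
    z = sy * cp * cr - cy * sp * sr
    q = np.stack([w, x, y, z], axis=-1)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def vector_magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(x^2 + y^2 + z^2) of a sensor triad."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError("triad channels must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def build_signal_set(
    stream: ImuStream,
    beta: float = 0.1,
    fc: float = 20.0,
    order: int = 8,
) -> SignalSet:
    """Derive the full 18-channel signal set from a raw recording.

    The six accelerometer/gyroscope channels are low-pass filtered; the
    magnetometer triad is passed through raw.  Orientation is estimated
    from the filtered inertial channels plus the raw magnetometer, then
    converted to Euler inclinations; the two magnitude signals are
    computed from the filtered triads.
    """
    stream.validate()
    acc_f = np.column_stack(
        [lowpass_filter(c, stream.fs, fc, order) for c in (stream.acc_x, stream.acc_y, stream.acc_z)]
    )
    gyro_f = np.column_stack(
        [lowpass_filter(c, stream.fs, fc, order) for c in (stream.gyro_x, stream.gyro_y, stream.gyro_z)]
    )
    mag = stream.mag
    quat = estimate_orientation(acc_f, gyro_f * DEG2RAD, mag, fs=stream.fs, beta=beta)
    pitch, roll, yaw = quaternion_to_euler(quat)
    channels = {
        "acc_x": acc_f[:, 0], "acc_y": acc_f[:, 1], "acc_z": acc_f[:, 2],
        "gyro_x": gyro_f[:, 0], "gyro_y": gyro_f[:, 1], "gyro_z": gyro_f[:, 2],
        "mag_x": mag[:, 0], "mag_y": mag[:, 1], "mag_z": mag[:, 2],
        "quat_w": quat[:, 0], "quat_x": quat[:, 1], "quat_y": quat[:, 2], "quat_z": quat[:, 3],
        "pitch": pitch, "roll": roll, "yaw": yaw,
        "acc_mag": vector_magnitude(acc_f[:, 0], acc_f[:, 1], acc_f[:, 2]),
        "gyro_mag": vector_magnitude(gyro_f[:, 0], gyro_f[:, 1], gyro_f[:, 2]),
    }
    return SignalSet(
        channels=channels,
        fs=stream.fs,
        session_id=stream.session_id,
        exercise=stream.exercise,
        meta={"beta": beta, "fc": fc, "order": order},
    )
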