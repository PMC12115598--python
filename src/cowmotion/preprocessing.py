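"""Raw-count scaling and body-frame -> world-frame rotation.

The collar ADCs emit signed integer counts. Physical units are recovered by
linear scaling with the configured full-scale range and bit depth:

    a [m/s^2] = raw * Range_a / 2^b_a * 9.807
    w [deg/s] = raw * Range_w / 2^b_w

Orientation arrives as a unit quaternion from the on-board sensor fusion
(scalar-first, right-handed Hamilton convention). Rotating the body-frame
specific force by that quaternion aligns it with the terrestrial frame, so
gravity sits on the world z axis. Gravity is retained: the rotated quantity
is specific force, not gravity-compensated linear acceleration. Gyroscope
and magnetometer channels are never rotated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: m/s^2 per g
GRAVITY = 9.807


class RangeError(ValueError):
    """Raw count outside the ADC's representable range."""


@dataclass(frozen=True)
class SensorSpec:
    """ADC full-scale ranges and bit depths of one IMU."""

    accel_range_g: float
    accel_bits: int
    gyro_range_dps: float
    gyro_bits: int

    def __post_init__(self):
        if self.accel_range_g <= 0 or self.gyro_range_dps <= 0:
            raise ValueError("ranges must be positive")
        for b in (self.accel_bits, self.gyro_bits):
            if not 8 <= b <= 32:
                raise ValueError(f"bit depth {b} outside 8..32")

    @property
    def accel_lsb(self) -> float:
        """m/s^2 per count."""
        return self.accel_range_g / 2 ** self.accel_bits * GRAVITY

    @property
    def gyro_lsb(self) -> float:
        """deg/s per count."""
        return self.gyro_range_dps / 2 ** self.gyro_bits


#: shipped presets (editable; the range/bit mapping is a sensor-dialect choice)
BNO055 = SensorSpec(accel_range_g=8, accel_bits=14, gyro_range_dps=2000, gyro_bits=16)
MPU9250 = SensorSpec(accel_range_g=16, accel_bits=16, gyro_range_dps=2000, gyro_bits=16)

SENSOR_PRESETS = {"BNO055": BNO055, "MPU9250": MPU9250}


def raw_to_accel(raw, spec: SensorSpec):
    """Scale raw accelerometer counts to m/s^2."""
    raw = np.asarray(raw)
    if np.any(np.abs(raw) >= 2 ** spec.accel_bits):
        raise RangeError(f"accelerometer count exceeds {spec.accel_bits}-bit range")
    return raw * spec.accel_lsb


def raw_to_gyro(raw, spec: SensorSpec):
    """Scale raw gyroscope counts to deg/s."""
    raw = np.asarray(raw)
    if np.any(np.abs(raw) >= 2 ** spec.gyro_bits):
        raise RangeError(f"gyroscope count exceeds {spec.gyro_bits}-bit range")
    return raw * spec.gyro_lsb


def accel_to_raw(value, spec: SensorSpec):
    """Nearest-integer inverse of :func:`raw_to_accel`.

    Raises :class:`RangeError` if the count would clip.
    """
    counts = np.rint(np.asarray(value, dtype=float) / spec.accel_lsb).astype(np.int64)
    if np.any(np.abs(counts) >= 2 ** spec.accel_bits):
        raise RangeError("acceleration exceeds representable ADC range")
    return counts


def gyro_to_raw(value, spec: SensorSpec):
    """Nearest-integer inverse of :func:`raw_to_gyro`."""
    counts = np.rint(np.asarray(value, dtype=float) / spec.gyro_lsb).astype(np.int64)
    if np.any(np.abs(counts) >= 2 ** spec.gyro_bits):
        raise RangeError("angular rate exceeds representable ADC range")
    return counts


def normalize_quaternion(q):
    """Return q / ||q|| as an array (w, x, y, z); error on the zero quaternion."""
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError("quaternion must have 4 components (w, x, y, z)")
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("zero quaternion has no orientation")
    return q / norm


def quat_to_rotation(q) -> np.ndarray:
    """Rotation matrix of a (scalar-first) unit quaternion.

    The input is normalized internally; the result is orthonormal with
    determinant +1. Applied to a body-frame vector it yields the
    world-frame vector.
    """
    w, x, y, z = normalize_quaternion(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quat_multiply(p, q):
    """Hamilton product p*q, scalar-first."""
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array([
        pw * qw - px * qx - py * qy - pz * qz,
        pw * qx + px * qw + py * qz - pz * qy,
        pw * qy - px * qz + py * qw + pz * qx,
        pw * qz + px * qy - py * qx + pz * qw,
    ])


def quat_conjugate(q):
    w, x, y, z = q
    return np.array([w, -x, -y, -z])


def rotate_to_world(a_body, q) -> np.ndarray:
    """Rotate body-frame vector(s) into the world frame: a_w = R(q) a_b.

    ``a_body`` may be a single (3,) vector or an (n, 3) array paired with a
    single quaternion or an (n, 4) quaternion trace.
    """
    a_body = np.asarray(a_body, dtype=float)
    q = np.asarray(q, dtype=float)
    if a_body.ndim == 1:
        return quat_to_rotation(q) @ a_body
    if q.ndim == 1:
        return a_body @ quat_to_rotation(q).T
    if len(q) != len(a_body):
        raise ValueError("per-sample quaternion trace length mismatch")
    out = np.empty_like(a_body)
    for i in range(len(a_body)):
        out[i] = quat_to_rotation(q[i]) @ a_body[i]
    return out


def rotate_to_body(a_world, q) -> np.ndarray:
    """Inverse of :func:`rotate_to_world` (rotation by the conjugate)."""
    a_world = np.asarray(a_world, dtype=float)
    q = np.asarray(q, dtype=float)
    if q.ndim == 1:
        qc = quat_conjugate(normalize_quaternion(q))
    else:
        qc = np.column_stack([q[:, 0], -q[:, 1], -q[:, 2], -q[:, 3]])
    return rotate_to_world(a_world, qc)
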