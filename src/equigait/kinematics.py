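"""Per-sensor kinematic channel derivation.

From each sensor's raw streams this module derives the channel set used
by the downstream stride comparison:

* ``acc_x/y/z``, ``gyro_x/y/z`` — raw sensor-frame streams;
* ``acc_vert``, ``acc_horiz`` — gravity-free acceleration resolved in
  the global frame: vertical component (signed) and horizontal planar
  norm (non-negative);
* ``angle_xv/yv/zv`` — unsigned angle (degrees, in [0, 180]) between
  each sensor axis and the earth vertical;
* ``swing``, ``twist`` — cannon sensors only: signed angles (degrees)
  of the swing–twist decomposition of the attitude relative to the
  per-recording mean attitude, with the twist axis along the sensor x
  axis (the limb longitudinal axis).

That is 11 channels for head/trunk sensors and 13 for cannons.

Quaternions are scalar-first Hamilton, sensor-to-global; q and -q are
treated as the same rotation (canonicalized to non-negative scalar
part).  Gravity is removed before resolving components, so a static
sensor reads zero on acc_vert/acc_horiz regardless of attitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .datamodel import GRAVITY, SensorLocation, SensorRecording, ValidationError

BASE_CHANNELS = [
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "acc_vert", "acc_horiz",
    "angle_xv", "angle_yv", "angle_zv",
]
CANNON_CHANNELS = BASE_CHANNELS + ["swing", "twist"]

__all__ = [
    "BASE_CHANNELS",
    "CANNON_CHANNELS",
    "ChannelSet",
    "resolve_global_acceleration",
    "axis_vertical_angles",
    "swing_twist",
    "swing_twist_angles",
    "swing_twist_decompose",
    "derive_channels",
    "mean_attitude",
    "quat_canonical",
    "quat_multiply",
    "quat_conjugate",
]


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first Hamilton)


def quat_canonical(q: np.ndarray) -> np.ndarray:
    """Map q -> -q where the scalar part is negative (double cover)."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    return q * sign


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    out = np.array(q, dtype=float, copy=True)
    out[..., 1:] *= -1.0
    return out


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b (broadcasting, scalar-first)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(a, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def _as_rotation(quat: np.ndarray) -> Rotation:
    return Rotation.from_quat(np.asarray(quat, dtype=float), scalar_first=True)


def mean_attitude(quat: np.ndarray) -> np.ndarray:
    """Normalized mean quaternion (signs aligned to the first sample).

    An adequate barycenter for the small attitude spreads seen within a
    passage; exact Karcher averaging is unnecessary here.
    """
    q = quat_canonical(np.asarray(quat, dtype=float))
    # align hemispheres with the first sample before averaging
    sign = np.where(q @ q[0] < 0, -1.0, 1.0)
    m = (q * sign[:, None]).mean(axis=0)
    n = np.linalg.norm(m)
    if n < 1e-12:
        raise ValidationError("mean attitude undefined (quaternions cancel)")
    return quat_canonical(m / n)


# ---------------------------------------------------------------------------
# channel operations


def resolve_global_acceleration(rec: SensorRecording) -> tuple[np.ndarray, np.ndarray]:
    """Gravity-free global acceleration: (vertical component, horizontal norm).

    Per sample: a_g = R(quat)·acc − g·ẑ;  acc_vert = a_g·ẑ;
    acc_horiz = ||(a_g·x̂, a_g·ŷ)||.
    """
    a_g = _as_rotation(rec.quat).apply(rec.acc)
    a_g[:, 2] -= GRAVITY
    acc_vert = a_g[:, 2].copy()
    acc_horiz = np.hypot(a_g[:, 0], a_g[:, 1])
    return acc_vert, acc_horiz


def axis_vertical_angles(rec: SensorRecording) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Angle of each sensor axis to the earth vertical, degrees in [0, 180].

    angle_iv = arccos( clamp( (R(quat)·ê_i)·ẑ, −1, 1) ).
    """
    R = _as_rotation(rec.quat).as_matrix()  # columns: sensor axes in global frame
    cosines = np.clip(R[:, 2, :], -1.0, 1.0)  # z-row = vertical components
    angles = np.degrees(np.arccos(cosines))
    return angles[:, 0], angles[:, 1], angles[:, 2]


def swing_twist_decompose(q_rel: np.ndarray, twist_axis) -> tuple[np.ndarray, np.ndarray]:
    """Factor relative rotations as q_rel = q_swing ⊗ q_twist.

    q_twist is the rotation about ``twist_axis``; q_swing's axis is
    orthogonal to it.  For the degenerate case (180-degree rotation
    exactly orthogonal to the twist axis) q_twist is the identity.
    """
    q_rel = np.atleast_2d(np.asarray(q_rel, dtype=float))
    axis = np.asarray(twist_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    w = q_rel[..., 0]
    proj = q_rel[..., 1:] @ axis
    tw = np.stack([w, proj * axis[0], proj * axis[1], proj * axis[2]], axis=-1)
    tw_norm = np.linalg.norm(tw, axis=-1)
    degenerate = tw_norm < 1e-12
    q_twist = tw / np.where(degenerate, 1.0, tw_norm)[..., None]
    q_twist[degenerate] = np.array([1.0, 0.0, 0.0, 0.0])
    q_swing = quat_multiply(q_rel, quat_conjugate(q_twist))
    return q_swing, q_twist


def swing_twist_angles(
    quat: np.ndarray,
    twist_axis=(1.0, 0.0, 0.0),
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Swing and twist angles (degrees, signed) of attitudes vs a reference.

    The relative rotation q_rel = q_ref⁻¹ ⊗ q is factored as
    q_rel = q_swing ⊗ q_twist with q_twist about ``twist_axis`` (sensor
    frame) and the swing axis orthogonal to it.  Twist is signed by the
    right-hand rule about +twist_axis; swing is signed by the projection
    of its axis on the sensor lateral (y) direction, ties resolved to +.

    Returns (swing_deg, twist_deg, degenerate_mask); where the relative
    rotation is a 180-degree turn exactly orthogonal to the twist axis,
    twist is undefined and reported as 0 with the mask set.
    """
    quat = np.asarray(quat, dtype=float)
    axis = np.asarray(twist_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if reference is None:
        reference = mean_attitude(quat)
    q_rel = quat_canonical(quat_multiply(quat_conjugate(reference), quat))

    w = q_rel[..., 0]
    proj = q_rel[..., 1:] @ axis
    q_swing, q_twist = swing_twist_decompose(q_rel, axis)
    degenerate = np.linalg.norm(
        np.stack([w, proj], axis=-1), axis=-1) < 1e-12

    twist = 2.0 * np.arctan2(proj, w)
    twist = np.where(degenerate, 0.0, twist)

    sw_w = np.clip(q_swing[..., 0], -1.0, 1.0)
    sw_v = q_swing[..., 1:]
    sw_mag = np.linalg.norm(sw_v, axis=-1)
    swing = 2.0 * np.arctan2(sw_mag, sw_w)
    lateral = sw_v[..., 1]  # sensor y component of the swing axis
    sign = np.where(lateral < 0, -1.0, 1.0)
    swing = sign * swing

    return np.degrees(swing), np.degrees(twist), degenerate


def swing_twist(
    rec: SensorRecording,
    twist_axis=(1.0, 0.0, 0.0),
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Swing/twist channels for a cannon recording (degrees, signed)."""
    if not rec.location.is_cannon:
        raise ValidationError(
            f"swing–twist is defined for cannon sensors only, got {rec.location.key}"
        )
    swing, twist, _ = swing_twist_angles(rec.quat, twist_axis, reference)
    return swing, twist


@dataclass
class ChannelSet:
    """Derived kinematic channels for one sensor (ordered name -> series)."""

    location: SensorLocation
    fs: float
    channels: dict

    def __post_init__(self) -> None:
        expected = CANNON_CHANNELS if self.location.is_cannon else BASE_CHANNELS
        if list(self.channels) != expected:
            raise ValidationError(
                f"sensor {self.location.key}: expected channels {expected}, "
                f"got {list(self.channels)}"
            )
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValidationError(
                f"sensor {self.location.key}: channel length mismatch {lengths}"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def to_dataframe(self):
        """Channels as a DataFrame with a time column (s), one column each."""
        import pandas as pd

        n = len(next(iter(self.channels.values())))
        data = {"t": np.arange(n) / self.fs}
        data.update(self.channels)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        """Write channels in the same CSV dialect as recording containers."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def derive_channels(rec: SensorRecording) -> ChannelSet:
    """Assemble the full channel set (13 for cannons, 11 otherwise)."""
    acc_vert, acc_horiz = resolve_global_acceleration(rec)
    angle_xv, angle_yv, angle_zv = axis_vertical_angles(rec)
    channels = {
        "acc_x": rec.acc[:, 0], "acc_y": rec.acc[:, 1], "acc_z": rec.acc[:, 2],
        "gyro_x": rec.gyro[:, 0], "gyro_y": rec.gyro[:, 1], "gyro_z": rec.gyro[:, 2],
        "acc_vert": acc_vert, "acc_horiz": acc_horiz,
        "angle_xv": angle_xv, "angle_yv": angle_yv, "angle_zv": angle_zv,
    }
    if rec.location.is_cannon:
        swing, twist = swing_twist(rec)
        channels["swing"] = swing
        channels["twist"] = twist
    return ChannelSet(location=rec.location, fs=rec.fs, channels=channels)
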