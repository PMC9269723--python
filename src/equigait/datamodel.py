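"""Core data model: sensor locations, recordings, and sessions.

A measurement session is one horse measured at one gait in one run
(before or after the training session).  Each run consists of one or
more corridor passages; during a passage every body-mounted IMU records
time-synchronized 3-axis acceleration (sensor frame, m/s^2, gravity
included), 3-axis angular velocity (sensor frame, rad/s) and a unit
orientation quaternion rotating the sensor frame into the global frame
(scalar-first Hamilton convention).

Global frame convention: right-handed, +Z up, gravity magnitude
``GRAVITY`` = 9.81 m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

GRAVITY = 9.81
QUAT_NORM_TOL = 1e-6

__all__ = [
    "GRAVITY",
    "Gait",
    "Run",
    "Side",
    "LocationCode",
    "SensorLocation",
    "SensorRecording",
    "Session",
    "ValidationError",
    "STANDARD_LOCATIONS",
]


class ValidationError(ValueError):
    """A recording or session violates a structural invariant."""


class Gait(str, Enum):
    TROT = "trot"
    CANTER = "canter"


class Run(str, Enum):
    BEFORE = "before"
    AFTER = "after"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"


class LocationCode(str, Enum):
    FH = "FH"  # forehead
    PO = "PO"  # poll
    WI = "WI"  # withers
    ST = "ST"  # sternum
    SA = "SA"  # sacrum
    FC = "FC"  # forelimb cannon
    HC = "HC"  # hindlimb cannon


#: codes that designate limb (cannon) sensors and therefore carry a side
CANNON_CODES = frozenset({LocationCode.FC, LocationCode.HC})


@dataclass(frozen=True)
class SensorLocation:
    """Anatomical placement of one IMU.

    Cannon sensors (FC/HC) must be lateralized; all trunk/head sensors
    are midline.
    """

    code: LocationCode
    side: Side = Side.MIDLINE

    def __post_init__(self) -> None:
        code = LocationCode(self.code)
        side = Side(self.side)
        object.__setattr__(self, "code", code)
        object.__setattr__(self, "side", side)
        if code in CANNON_CODES:
            if side not in (Side.LEFT, Side.RIGHT):
                raise ValidationError(
                    f"{code.value} sensor must carry side left or right, got {side.value}"
                )
        elif side is not Side.MIDLINE:
            raise ValidationError(
                f"{code.value} sensor is midline, got side {side.value}"
            )

    @property
    def is_cannon(self) -> bool:
        return self.code in CANNON_CODES

    @property
    def key(self) -> str:
        """Compact label, e.g. ``ST`` or ``FC_L``."""
        if self.is_cannon:
            return f"{self.code.value}_{'L' if self.side is Side.LEFT else 'R'}"
        return self.code.value

    @classmethod
    def from_key(cls, key: str) -> "SensorLocation":
        parts = key.split("_")
        try:
            code = LocationCode(parts[0])
        except ValueError as exc:
            raise ValidationError(f"unknown location code {key!r}") from exc
        if len(parts) == 1:
            return cls(code)
        side = {"L": Side.LEFT, "R": Side.RIGHT}.get(parts[1])
        if side is None:
            raise ValidationError(f"unknown location code {key!r}")
        return cls(code, side)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


#: the nine-sensor layout used throughout: head (forehead, poll), trunk
#: (withers, sternum, sacrum) and the four cannon sensors.
STANDARD_LOCATIONS: tuple[SensorLocation, ...] = (
    SensorLocation(LocationCode.FH),
    SensorLocation(LocationCode.PO),
    SensorLocation(LocationCode.WI),
    SensorLocation(LocationCode.ST),
    SensorLocation(LocationCode.SA),
    SensorLocation(LocationCode.FC, Side.LEFT),
    SensorLocation(LocationCode.FC, Side.RIGHT),
    SensorLocation(LocationCode.HC, Side.LEFT),
    SensorLocation(LocationCode.HC, Side.RIGHT),
)


@dataclass
class SensorRecording:
    """One sensor's synchronized streams for one passage.

    Parameters
    ----------
    location
        Anatomical placement.
    fs
        Sampling rate in Hz (constant over the recording).
    acc
        (T, 3) specific force in the sensor frame, m/s^2 (gravity included).
    gyro
        (T, 3) angular velocity in the sensor frame, rad/s.
    quat
        (T, 4) unit quaternions, scalar-first, rotating sensor frame into
        the global frame.
    """

    location: SensorLocation
    fs: float
    acc: np.ndarray
    gyro: np.ndarray
    quat: np.ndarray

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        self.validate()

    def validate(self) -> None:
        loc = self.location.key
        if not self.fs > 0:
            raise ValidationError(f"sensor {loc}: sampling rate must be > 0")
        for name, arr, width in (
            ("acc", self.acc, 3),
            ("gyro", self.gyro, 3),
            ("quat", self.quat, 4),
        ):
            if arr.ndim != 2 or arr.shape[1] != width:
                raise ValidationError(
                    f"sensor {loc}: stream {name} must be (T, {width}), got {arr.shape}"
                )
        T = self.acc.shape[0]
        if self.gyro.shape[0] != T or self.quat.shape[0] != T:
            raise ValidationError(
                f"sensor {loc}: stream length mismatch "
                f"(acc {T}, gyro {self.gyro.shape[0]}, quat {self.quat.shape[0]})"
            )
        if T < 2 * self.fs:
            raise ValidationError(
                f"sensor {loc}: recording shorter than 2 s ({T} samples at {self.fs} Hz)"
            )
        norms = np.linalg.norm(self.quat, axis=1)
        bad = np.abs(norms - 1.0) > QUAT_NORM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValidationError(
                f"sensor {loc}: non-unit quaternion at sample {i} (norm {norms[i]:.6g})"
            )

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def equals(self, other: "SensorRecording", atol: float = 0.0) -> bool:
        return (
            self.location == other.location
            and self.fs == other.fs
            and np.allclose(self.acc, other.acc, atol=atol, rtol=0)
            and np.allclose(self.gyro, other.gyro, atol=atol, rtol=0)
            and np.allclose(self.quat, other.quat, atol=atol, rtol=0)
        )


#: one corridor passage: mapping of location key -> SensorRecording
Passage = dict


@dataclass
class Session:
    """All passages of one (horse, gait, run) measurement.

    ``passages`` is a list of dicts mapping location keys (``"ST"``,
    ``"FC_L"``, ...) to :class:`SensorRecording`; all sensors within a
    passage share fs and length (time-synchronized).  ``truth`` holds
    generator ground truth (stride onset times, generating global
    accelerations) when the session is synthetic; it is never required
    by the analysis pipeline.
    """

    horse_id: str
    gait: Gait
    run: Run
    passages: list
    truth: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gait = Gait(self.gait)
        self.run = Run(self.run)
        self.validate()

    def validate(self) -> None:
        if not self.passages:
            raise ValidationError("session must contain at least one passage")
        for p_idx, passage in enumerate(self.passages):
            if not passage:
                raise ValidationError(f"passage {p_idx} has no sensors")
            shapes = {(rec.fs, rec.n_samples) for rec in passage.values()}
            if len(shapes) != 1:
                raise ValidationError(
                    f"passage {p_idx}: sensors not time-synchronized "
                    f"(fs, T pairs: {sorted(shapes)})"
                )
            for key, rec in passage.items():
                if key != rec.location.key:
                    raise ValidationError(
                        f"passage {p_idx}: key {key!r} does not match "
                        f"sensor location {rec.location.key!r}"
                    )

    @property
    def fs(self) -> float:
        return next(iter(self.passages[0].values())).fs

    def sensor_keys(self) -> list:
        return sorted(self.passages[0].keys())

    def equals(self, other: "Session", atol: float = 0.0) -> bool:
        if (
            self.horse_id != other.horse_id
            or self.gait != other.gait
            or self.run != other.run
            or len(self.passages) != len(other.passages)
        ):
            return False
        for pa, pb in zip(self.passages, other.passages):
            if sorted(pa) != sorted(pb):
                return False
            if not all(pa[k].equals(pb[k], atol=atol) for k in pa):
                return False
        return True
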