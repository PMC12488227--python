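"""Domain types: sensor streams, trial recordings, segment pairs.

Conventions fixed once, package-wide:

* Quaternions are scalar-first ``(w, x, y, z)``, Hamilton product,
  sensor-to-global passive rotation.
* Time is in seconds at all public interfaces (nominal sampling 62.5 Hz),
  angles in degrees, gyro in deg/s, accelerometer in g units.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import StreamError

FS_NOMINAL = 62.5  #: nominal sampling rate, Hz
QUAT_NORM_TOL = 1e-3  #: max |quat|-1 accepted before renormalization


class Sensor(str, enum.Enum):
    """The four body-worn sensors: upper thoracic, thoracolumbar, lumbosacral, femur."""

    T1 = "T1"
    L1 = "L1"
    L5 = "L5"
    HIP = "HIP"


class TestId(str, enum.Enum):
    """The synchronization choreography plus the nine movement tests."""

    SYNC = "SYNC"
    AR_SELF = "AR_SELF"    # self-paced axial rotation
    LB_SELF = "LB_SELF"    # self-paced lateral bending
    FE_SELF = "FE_SELF"    # self-paced flexion/extension
    AR_FAST = "AR_FAST"    # fast-paced axial rotation
    LB_FAST = "LB_FAST"    # fast-paced lateral bending
    FLEX_FAST = "FLEX_FAST"  # fast-paced flexion
    CRF = "CRF"            # coupled rotation/flexion
    FSTS = "FSTS"          # five times sit-to-stand
    PLS = "PLS"            # postural lifting strategy


class Pace(str, enum.Enum):
    SELF = "self"
    FAST = "fast"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    INTERSEX = "intersex"
    UNKNOWN = "unknown"


#: pace of each test (SYNC treated as self-paced choreography)
TEST_PACE: dict[TestId, Pace] = {
    TestId.SYNC: Pace.SELF,
    TestId.AR_SELF: Pace.SELF,
    TestId.LB_SELF: Pace.SELF,
    TestId.FE_SELF: Pace.SELF,
    TestId.AR_FAST: Pace.FAST,
    TestId.LB_FAST: Pace.FAST,
    TestId.FLEX_FAST: Pace.FAST,
    TestId.CRF: Pace.FAST,
    TestId.FSTS: Pace.FAST,
    TestId.PLS: Pace.FAST,
}


class SegmentPair(enum.Enum):
    """Sensor pairs defining the four analysed regions.

    ``moving`` is the sensor whose anatomical frame is expressed in the
    frame of ``reference`` (the region's relative rotation): trunk = T1
    relative to L5, thoracic = T1 relative to L1, lumbar = L1 relative to
    L5, hip = L5 relative to the femur sensor.
    """

    TRUNK = ("TRUNK", Sensor.L5, Sensor.T1)
    THORACIC = ("THORACIC", Sensor.L1, Sensor.T1)
    LUMBAR = ("LUMBAR", Sensor.L5, Sensor.L1)
    HIP = ("HIP", Sensor.HIP, Sensor.L5)

    def __init__(self, label: str, reference: Sensor, moving: Sensor):
        self.label = label
        self.reference = reference
        self.moving = moving

    @property
    def proximal(self) -> Sensor:
        """Reference sensor (frame in which the relative rotation is expressed)."""
        return self.reference

    @property
    def distal(self) -> Sensor:
        """Moving sensor."""
        return self.moving


@dataclass
class SensorStream:
    """One sensor's synchronized time series.

    Attributes
    ----------
    sensor_id : Sensor
    t : (n,) float array, seconds, strictly increasing
    quat : (n, 4) float array, scalar-first unit quaternions, sensor-to-global
    gyro : (n, 3) float array, deg/s, sensor frame
    accel : (n, 3) float array, g units, sensor frame
    """

    sensor_id: Sensor
    t: np.ndarray
    quat: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def fs(self) -> float:
        """Median sampling rate of the stream, Hz."""
        if len(self.t) < 2:
            return FS_NOMINAL
        return 1.0 / float(np.median(np.diff(self.t)))

    def validate(self) -> "SensorStream":
        """Check invariants in place; renormalize quaternions within tolerance.

        Raises
        ------
        StreamError
            Non-monotonic time, mismatched channel lengths, or a quaternion
            whose norm deviates from 1 by more than ``QUAT_NORM_TOL``.
        """
        n = len(self.t)
        if n < 1:
            raise StreamError(f"{self.sensor_id.value}: empty stream")
        for name, arr, width in (("quat", self.quat, 4), ("gyro", self.gyro, 3),
                                 ("accel", self.accel, 3)):
            if arr.shape != (n, width):
                raise StreamError(
                    f"{self.sensor_id.value}: {name} shape {arr.shape} != ({n}, {width})")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise StreamError(f"{self.sensor_id.value}: time not strictly increasing")
        norms = np.linalg.norm(self.quat, axis=1)
        bad = np.abs(norms - 1.0) > QUAT_NORM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise StreamError(
                f"{self.sensor_id.value}: quaternion norm {norms[i]:.4f} at sample {i}")
        # renormalize only meaningfully off-unit samples so validation is
        # idempotent at the bit level (write -> read -> write determinism)
        off = np.abs(norms - 1.0) > 1e-12
        if np.any(off):
            self.quat = self.quat.copy()
            self.quat[off] /= norms[off, None]
        return self

    def crop(self, start: int, stop: int | None = None) -> "SensorStream":
        """Return a copy restricted to samples ``[start, stop)``."""
        sl = slice(start, stop)
        return SensorStream(self.sensor_id, self.t[sl].copy(), self.quat[sl].copy(),
                            self.gyro[sl].copy(), self.accel[sl].copy())

    def copy(self) -> "SensorStream":
        return self.crop(0, None)


@dataclass
class TrialRecording:
    """A participant's recording of one test: up to four synchronized streams."""

    participant_id: str
    test_id: TestId
    pace: Pace
    streams: dict[Sensor, SensorStream]
    sex: Sex = Sex.UNKNOWN
    age: float = float("nan")
    fs: float = FS_NOMINAL

    @property
    def missing_sensors(self) -> list[Sensor]:
        return [s for s in Sensor if s not in self.streams]

    def validate(self) -> "TrialRecording":
        for s in self.streams.values():
            s.validate()
        return self

    def n_samples(self) -> int:
        """Common stream length (0 if no streams)."""
        if not self.streams:
            return 0
        return min(len(s) for s in self.streams.values())
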