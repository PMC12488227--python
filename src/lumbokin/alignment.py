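"""Stomp synchronization and anatomical alignment from the calibration
choreography.

The choreography (stomp, quiet standing, forward bend, right thigh lift,
with quiet gaps between) identifies, per sensor:

* the **vertical body axis** — the mean accelerometer direction during
  quiet standing (gravity reaction points superior);
* the **mediolateral axis** — the dominant gyroscope rotation axis during
  the forward bend (spinal sensors) or the thigh lift (femur sensor),
  signed so the initial movement is a positive rotation;
* the full frame by cross products (third axis = vertical x horizontal,
  then a final cross product restores exact orthogonality).

The rows of each returned matrix are the anatomical X (longitudinal),
Y (mediolateral) and Z (anteroposterior) axes expressed in the sensor
frame, i.e. the matrix maps sensor-local vectors to anatomical ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (AxisNotDominant, DegenerateAxes, DegenerateWindow,
                     NoStompFound)
from .types import Sensor, SensorStream, TrialRecording

STOMP_THRESHOLD_G = 2.0      #: default |accel magnitude - 1 g| threshold
QUIET_RMS_DPS = 3.0          #: gyro RMS below which a span counts as quiet
QUIET_MIN_S = 2.0            #: minimum quiet-span duration
ACTIVE_GYRO_DPS = 10.0       #: smoothed gyro magnitude marking movement
ACTIVE_MIN_S = 0.5           #: minimum movement-event duration
DOMINANCE_MIN = 0.6          #: minimum fraction of gyro variance on one axis


@dataclass
class AlignmentResult:
    """Per-sensor IMU-to-anatomical matrices plus provenance."""

    matrices: dict[Sensor, np.ndarray]
    stomp_index: int
    quality: dict[Sensor, float] = field(default_factory=dict)
    windows: dict[Sensor, dict[str, tuple[int, int]]] = field(default_factory=dict)
    missing: list[Sensor] = field(default_factory=list)
    errors: dict[Sensor, str] = field(default_factory=dict)

    @classmethod
    def identity(cls) -> "AlignmentResult":
        """Identity alignment for all sensors (ideal rig, already-anatomical IMUs)."""
        return cls({s: np.eye(3) for s in Sensor}, stomp_index=0,
                   quality={s: 1.0 for s in Sensor})


# ------------------------------------------------------------ detection


def detect_stomp(streams: dict[Sensor, SensorStream] | TrialRecording,
                 threshold: float = STOMP_THRESHOLD_G) -> int:
    """Earliest sample at which any sensor's accelerometer magnitude
    deviates from 1 g by more than ``threshold``.

    Raises ``NoStompFound`` when no sensor crosses the threshold.
    """
    if isinstance(streams, TrialRecording):
        streams = streams.streams
    best = None
    for s in streams.values():
        dev = np.abs(np.linalg.norm(s.accel, axis=1) - 1.0)
        hits = np.flatnonzero(dev > threshold)
        if hits.size:
            best = int(hits[0]) if best is None else min(best, int(hits[0]))
    if best is None:
        raise NoStompFound(f"no accelerometer deviation above {threshold} g")
    return best


def synchronize(rec: TrialRecording,
                threshold: float = STOMP_THRESHOLD_G) -> tuple[TrialRecording, int]:
    """Crop all streams to start at the stomp sample."""
    idx = detect_stomp(rec, threshold)
    streams = {s: st.crop(idx) for s, st in rec.streams.items()}
    rec2 = TrialRecording(rec.participant_id, rec.test_id, rec.pace, streams,
                          rec.sex, rec.age, rec.fs)
    return rec2, idx


def _smoothed_gyro_mag(s: SensorStream, window_s: float = 0.4) -> np.ndarray:
    mag = np.linalg.norm(s.gyro, axis=1)
    w = max(1, int(round(window_s * s.fs)))
    kernel = np.ones(w) / w
    return np.convolve(mag, kernel, mode="same")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index ranges of True runs."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _noise_floor(smoothed: np.ndarray) -> float:
    """Gyro noise floor estimate: the calibration trial is mostly quiet
    standing, so the median smoothed magnitude tracks the noise level."""
    return float(np.median(smoothed))


def find_quiet_window(s: SensorStream, min_duration: float = QUIET_MIN_S,
                      rms_thresh: float = QUIET_RMS_DPS) -> tuple[int, int]:
    """Longest gyro-quiet span of at least ``min_duration`` seconds.

    The quiet criterion is ``rms_thresh`` or 1.5x the trial's own noise
    floor, whichever is larger, so noisy gyros still yield a window.
    """
    smoothed = _smoothed_gyro_mag(s)
    thresh = max(rms_thresh, 1.5 * _noise_floor(smoothed))
    quiet = smoothed < thresh
    min_n = int(round(min_duration * s.fs))
    runs = [(a, b) for a, b in _runs(quiet) if b - a >= min_n]
    if not runs:
        raise DegenerateWindow(f"{s.sensor_id.value}: no quiet span >= "
                               f"{min_duration} s below {thresh:.1f} deg/s")
    return max(runs, key=lambda r: r[1] - r[0])


def find_movement_windows(s: SensorStream, level: float = ACTIVE_GYRO_DPS,
                          min_duration: float = ACTIVE_MIN_S
                          ) -> list[tuple[int, int]]:
    """Sample windows of sustained rotation (calibration movements), in
    order; the activity level floats above the trial's noise floor."""
    smoothed = _smoothed_gyro_mag(s)
    thresh = max(level, 3.0 * _noise_floor(smoothed))
    active = smoothed > thresh
    min_n = int(round(min_duration * s.fs))
    return [(a, b) for a, b in _runs(active) if b - a >= min_n]


# ----------------------------------------------------------- axis fitting


def estimate_vertical_axis(s: SensorStream, window: tuple[int, int]
                           ) -> np.ndarray:
    """Unit gravity-reaction direction (sensor frame) over a quiet window."""
    a, b = window
    mean = s.accel[a:b].mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 0.5:
        raise DegenerateWindow(
            f"{s.sensor_id.value}: mean accel norm {norm:.2f} g < 0.5 g")
    return mean / norm


def estimate_primary_horizontal_axis(s: SensorStream, window: tuple[int, int],
                                     movement: str = "bend"
                                     ) -> tuple[np.ndarray, float]:
    """Dominant gyro rotation axis over a movement window, and its quality.

    The axis is the first principal direction of the windowed gyro samples,
    signed so the initial (flexion / lift) rotation is positive about it.
    Returns ``(axis, quality)`` with quality = fraction of gyro variance
    explained; below ``DOMINANCE_MIN`` raises ``AxisNotDominant``.
    """
    a, b = window
    G = s.gyro[a:b]
    if len(G) < 3:
        raise AxisNotDominant(f"{s.sensor_id.value}: window too short")
    _, sv, Vt = np.linalg.svd(G, full_matrices=False)
    quality = float(sv[0] ** 2 / np.sum(sv ** 2))
    if quality < DOMINANCE_MIN:
        raise AxisNotDominant(
            f"{s.sensor_id.value}: {movement} axis explains only "
            f"{quality:.2f} of gyro variance")
    axis = Vt[0]
    proj = G @ axis
    strong = np.flatnonzero(np.abs(proj) > 0.3 * np.max(np.abs(proj)))
    if proj[strong[0]] < 0:
        axis = -axis
    return axis, quality


def build_anatomical_frame(vertical: np.ndarray,
                           horizontal: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame from the two estimated axes.

    Rows: X = vertical (longitudinal), Z = normalize(vertical x horizontal)
    (anteroposterior), Y = Z x X (mediolateral, the final cross product
    restoring orthogonality).  Raises ``DegenerateAxes`` when the inputs
    are within 10 degrees of parallel.
    """
    x = np.asarray(vertical, dtype=float)
    x = x / np.linalg.norm(x)
    h = np.asarray(horizontal, dtype=float)
    h = h / np.linalg.norm(h)
    if abs(float(np.dot(x, h))) > np.cos(np.deg2rad(10.0)):
        raise DegenerateAxes("vertical and horizontal axes within 10 deg "
                             "of parallel")
    z = np.cross(x, h)
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    # exact orthonormality by construction; polish determinant to +1
    assert np.linalg.det(R) > 0
    return R


# -------------------------------------------------------------- full trial


def align_trial(sync: TrialRecording,
                stomp_threshold: float = STOMP_THRESHOLD_G) -> AlignmentResult:
    """Run the full alignment on a synchronization recording.

    Spinal sensors take their mediolateral axis from their own first
    movement event after the stomp (the forward bend); the femur sensor
    from its own (the thigh lift — it is still during the bend).  Sensors
    whose sub-steps fail are reported in ``errors`` rather than aborting
    the others.
    """
    rec, stomp_idx = synchronize(sync, stomp_threshold)
    result = AlignmentResult({}, stomp_index=stomp_idx,
                             missing=rec.missing_sensors)
    for sensor, stream in rec.streams.items():
        movement = "thigh_lift" if sensor is Sensor.HIP else "bend"
        try:
            quiet = find_quiet_window(stream)
            vertical = estimate_vertical_axis(stream, quiet)
            moves = find_movement_windows(stream)
            if not moves:
                raise AxisNotDominant(
                    f"{sensor.value}: no movement event found for {movement}")
            horizontal, quality = estimate_primary_horizontal_axis(
                stream, moves[0], movement)
            result.matrices[sensor] = build_anatomical_frame(vertical,
                                                             horizontal)
            result.quality[sensor] = quality
            result.windows[sensor] = {"quiet": quiet, movement: moves[0]}
        except Exception as exc:  # noqa: BLE001 - per-sensor isolation
            result.errors[sensor] = f"{type(exc).__name__}: {exc}"
    return result
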