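"""Anatomical-frame dynamics and per-trial motion metrics.

Angular velocity comes directly from the gyroscope (low-pass filtered,
then rotated into the reference sensor's anatomical frame), never from
differentiated orientation; acceleration is the time derivative of that
velocity.  ROM metrics follow the per-test conventions in
:mod:`lumbokin.conventions`; trials failing the expected-movement screen
are rerouted through the gyroscope-integrated ROM, which ignores the
fused orientation channel entirely.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from . import conventions as conv
from .errors import NoRepsDetected, StreamError, TooShort
from .kinematics import EulerSeries, lowpass_zero_phase, quat_to_rotation
from .types import Pace, SegmentPair, TEST_PACE, TestId, TrialRecording


def _load_default_bounds() -> pd.DataFrame:
    with resources.files("lumbokin.data").joinpath(
            "physiologic_bounds.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class MetricsConfig:
    """Tunable thresholds of the metrics stage (all configurable; defaults
    documented in docs/methods.md)."""

    trim_fraction: float = 0.2          # symmetric trim of peak means
    angle_prominence: float = 5.0       # deg, rep detection on angle series
    velocity_prominence: float = 5.0    # deg/s, rep detection on velocity
    separation_fraction: float = 0.25   # of the expected rep period
    asymmetry_ratio: float = 3.0        # bilateral side-ratio flag
    direction_threshold: float = 2.0    # deg, first-excursion detection
    filter_gyro: bool = True
    bounds: pd.DataFrame = field(default_factory=_load_default_bounds)


@dataclass
class KinematicSeries:
    """Per-pair relative angular velocity/acceleration in the reference
    anatomical frame (columns: about-X, about-Y, about-Z), deg/s and deg/s^2."""

    velocity: dict[SegmentPair, np.ndarray]
    acceleration: dict[SegmentPair, np.ndarray]
    fs: float


@dataclass
class MotionMetrics:
    """Per-trial, per-pair summary in the reported sign conventions.

    ``rom_dir1``/``rom_dir2`` are the signed directional extremes; their
    meaning is given by ``directions`` (left/right for bilateral tests,
    flexion/extension for F/E).
    """

    test_id: TestId
    pair: SegmentPair
    directions: tuple[str, str] | None = None
    rom_dir1: float | None = None
    rom_dir2: float | None = None
    rom_total: float | None = None
    rom_mean: float | None = None
    vel_mean: float | None = None
    acc_mean: float | None = None
    n_reps: int | None = None
    method: str = "fusion"              # fusion | integrated
    flags: list[str] = field(default_factory=list)

    def rows(self, participant_id: str = "") -> list[dict]:
        """Tidy rows (one per metric) for CSV export."""
        out = []

        def add(metric, value, axis=""):
            if value is not None:
                out.append({"participant_id": participant_id,
                            "test_id": self.test_id.value,
                            "pair": self.pair.label, "metric": metric,
                            "axis": axis, "value": float(value),
                            "method": self.method,
                            "flags": ";".join(self.flags)})

        axis = conv.PRIMARY_AXIS.get(self.test_id, "")
        if self.directions:
            add(f"rom_{self.directions[0]}", self.rom_dir1, axis)
            add(f"rom_{self.directions[1]}", self.rom_dir2, axis)
        add("rom_total", self.rom_total, axis)
        add("rom_mean", self.rom_mean, axis)
        add("vel_mean", self.vel_mean, axis)
        add("acc_mean", self.acc_mean, axis)
        return out


# ------------------------------------------------------------- velocity


def anatomical_angular_velocity(trial: TrialRecording, align,
                                filter_gyro: bool = True
                                ) -> dict[SegmentPair, np.ndarray]:
    """Relative angular velocity per pair, reference anatomical frame.

    Per sensor the gyro is low-pass filtered and rotated to the global
    frame through the fused orientation; per pair the difference
    (moving - reference) is expressed in the reference sensor's anatomical
    frame.
    """
    omega_global = {}
    for sensor, stream in trial.streams.items():
        if stream.gyro.shape[1] != 3:
            raise StreamError(f"{sensor.value}: missing gyro channel")
        g = lowpass_zero_phase(stream.gyro, fs=stream.fs) if filter_gyro \
            else stream.gyro
        R = quat_to_rotation(stream.quat)
        omega_global[sensor] = np.einsum("nij,nj->ni", R, g)
    out = {}
    for pair in SegmentPair:
        if (pair.reference not in trial.streams
                or pair.moving not in trial.streams
                or pair.reference not in align.matrices
                or pair.moving not in align.matrices):
            continue
        ref = trial.streams[pair.reference]
        R_ref = quat_to_rotation(ref.quat)
        delta = omega_global[pair.moving] - omega_global[pair.reference]
        local = np.einsum("nji,nj->ni", R_ref, delta)
        out[pair] = np.einsum("ij,nj->ni", align.matrices[pair.reference],
                              local)
    return out


def differentiate_series(v: np.ndarray, fs: float) -> np.ndarray:
    """Central differences (one-sided at the ends), length preserving."""
    v = np.asarray(v, dtype=float)
    if v.shape[0] < 3:
        raise TooShort("differentiation needs >= 3 samples")
    return np.gradient(v, 1.0 / fs, axis=0)


def compute_kinematics(trial: TrialRecording, align,
                       filter_gyro: bool = True) -> KinematicSeries:
    """Velocity and acceleration series for every available pair."""
    vel = anatomical_angular_velocity(trial, align, filter_gyro)
    fs = trial.fs
    acc = {p: differentiate_series(v, fs) for p, v in vel.items()}
    return KinematicSeries(vel, acc, fs)


# ----------------------------------------------------------------- peaks


def extract_rep_peaks(x: np.ndarray, expected_reps: int | None = None,
                      polarity: str = "both", prominence: float = 5.0,
                      min_separation: int | None = None,
                      min_height_frac: float = 0.25
                      ) -> list[tuple[int, float]]:
    """Repetition extrema of a filtered series as (index, value) pairs.

    Maxima (and minima for ``polarity='both'``) with the given prominence
    and a minimum separation of a quarter of the expected repetition
    period.  Extrema smaller than ``min_height_frac`` of the largest
    magnitude are discarded — repetition peaks are the dominant
    excursions, and direction-change junctions otherwise register as
    small high-prominence artifacts.  Raises ``NoRepsDetected`` when
    nothing qualifies.
    """
    x = np.asarray(x, dtype=float)
    if min_separation is None:
        if expected_reps:
            min_separation = max(1, int(0.25 * len(x) / expected_reps))
        else:
            min_separation = 1
    peaks: list[tuple[int, float]] = []
    hi, _ = signal.find_peaks(x, prominence=prominence,
                              distance=min_separation)
    peaks += [(int(i), float(x[i])) for i in hi]
    if polarity == "both":
        lo, _ = signal.find_peaks(-x, prominence=prominence,
                                  distance=min_separation)
        peaks += [(int(i), float(x[i])) for i in lo]
    if peaks:
        floor = min_height_frac * max(abs(v) for _, v in peaks)
        peaks = [(i, v) for i, v in peaks if abs(v) >= floor]
    peaks.sort()
    if not peaks:
        raise NoRepsDetected(f"no peaks with prominence {prominence}")
    return peaks


def trimmed_mean_abs(values, trim_fraction: float = 0.2) -> float:
    """Mean of absolute values after dropping ``floor(trim*n)`` from each
    end of the sorted absolute values; trim 0 is the plain mean."""
    v = np.sort(np.abs(np.asarray(values, dtype=float).ravel()))
    if v.size == 0:
        raise ValueError("empty input")
    k = int(np.floor(trim_fraction * v.size))
    if v.size - 2 * k <= 0:
        k = 0
    return float(v[k: v.size - k].mean())


# ------------------------------------------------------------------- ROM


def rom_self_paced(e: EulerSeries, test_id: TestId,
                   config: MetricsConfig | None = None) -> MotionMetrics:
    """Directional and total ROM for the self-paced tests.

    The primary-axis series is read in the per-test reported sign
    convention; total ROM is the sum of the two directional magnitudes.
    """
    config = config or MetricsConfig()
    axis = conv.PRIMARY_AXIS[test_id]
    x = e.axis(axis)
    m = conv.report_sign(test_id, e.pair)
    family = conv.TEST_FAMILY[test_id]
    met = MotionMetrics(test_id, e.pair,
                        directions=conv.DIRECTION_LABELS[family],
                        rom_dir1=m * float(np.max(x)),
                        rom_dir2=m * float(np.min(x)),
                        rom_total=float(np.max(x) - np.min(x)))
    if e.gimbal_fraction > 0.05:
        met.flags.append("gimbal")
    return met


def rom_functional(e: EulerSeries, test_id: TestId,
                   expected_reps: int | None = None,
                   config: MetricsConfig | None = None) -> MotionMetrics:
    """Mean absolute per-repetition sagittal excursion (CRF / 5STS / PLS)."""
    config = config or MetricsConfig()
    expected = expected_reps or conv.EXPECTED_REPS[test_id]
    peaks = extract_rep_peaks(e.beta, expected, polarity="positive",
                              prominence=config.angle_prominence)
    values = np.abs([v for _, v in peaks])
    return MotionMetrics(test_id, e.pair, rom_mean=float(values.mean()),
                         n_reps=len(values))


def integrated_angle_series(trial: TrialRecording, align, pair: SegmentPair,
                            axis: str) -> np.ndarray:
    """Relative rotation angle about the cued anatomical axis by
    trapezoidal integration of the raw gyroscope channels.

    Each sensor's gyro is projected onto its own anatomical axis (a row of
    its constant alignment matrix); the moving-minus-reference difference
    is integrated.  The fused quaternion channel is never used, so the
    result is immune to sensor-fusion drift.
    """
    row = conv.AXIS_ROW[axis]
    comps = {}
    for sensor in (pair.reference, pair.moving):
        if sensor not in trial.streams:
            raise StreamError(f"{sensor.value}: stream missing")
        stream = trial.streams[sensor]
        comps[sensor] = stream.gyro @ align.matrices[sensor][row]
    rel = comps[pair.moving] - comps[pair.reference]
    fs = trial.streams[pair.reference].fs
    theta = cumulative_trapezoid(rel, dx=1.0 / fs, initial=0.0)
    return theta - theta[0]


def integrated_rom(trial: TrialRecording, align, pair: SegmentPair,
                   axis: str) -> float:
    """max - min of the gyroscope-integrated angle, degrees."""
    theta = integrated_angle_series(trial, align, pair, axis)
    return float(np.max(theta) - np.min(theta))


# ------------------------------------------------------------- screening


def flag_unexpected_movement(met: MotionMetrics, e: EulerSeries,
                             test_id: TestId,
                             config: MetricsConfig | None = None) -> list[str]:
    """Expected-movement screen: physiologic range, bilateral symmetry,
    cued global direction (left / flexion first).  Returns flag strings."""
    config = config or MetricsConfig()
    flags: list[str] = []
    family = conv.TEST_FAMILY[test_id]
    group = conv.pair_group(e.pair)
    tbl = config.bounds
    for quantity, value in (("rom_total", met.rom_total),
                            ("rom_mean", met.rom_mean),
                            ("vel_mean", met.vel_mean),
                            ("acc_mean", met.acc_mean)):
        if value is None:
            continue
        row = tbl[(tbl.family == family) & (tbl.pair_group == group)
                  & (tbl.quantity == quantity)]
        if len(row) and not (row.lower.iloc[0] <= abs(value)
                             <= row.upper.iloc[0]):
            flags.append("out_of_range")
    if (met.directions and family in ("AR", "LB")
            and met.rom_dir1 is not None and met.rom_dir2 is not None):
        lo = min(abs(met.rom_dir1), abs(met.rom_dir2))
        hi = max(abs(met.rom_dir1), abs(met.rom_dir2))
        if lo > 0 and hi / lo > config.asymmetry_ratio:
            flags.append("asymmetry")
        elif lo == 0 and hi > config.direction_threshold:
            flags.append("asymmetry")
    axis = conv.PRIMARY_AXIS[test_id]
    x = e.axis(axis)
    moving = np.flatnonzero(np.abs(x) > config.direction_threshold)
    if moving.size and x[moving[0]] < 0:
        # internal convention: the cued first direction (left / flexion)
        # is positive
        flags.append("wrong_direction")
    return sorted(set(flags))


# ----------------------------------------------------------- orchestration


def analyze_trial(trial: TrialRecording, align,
                  angles: dict[SegmentPair, EulerSeries],
                  kin: KinematicSeries | None = None,
                  config: MetricsConfig | None = None
                  ) -> list[MotionMetrics]:
    """All Table-1 metrics of one trial: ROM for the self-paced and
    functional tests, trimmed-mean velocity/acceleration for the
    fast-paced ones; flagged ROM reroutes through the integrated method."""
    config = config or MetricsConfig()
    test_id = trial.test_id
    if test_id not in conv.PRIMARY_AXIS:
        raise ValueError(f"{test_id} is not a movement test")
    axis = conv.PRIMARY_AXIS[test_id]
    fast = TEST_PACE[test_id] is Pace.FAST
    rom_test = test_id in (TestId.AR_SELF, TestId.LB_SELF, TestId.FE_SELF,
                           TestId.CRF, TestId.FSTS, TestId.PLS)
    if fast and kin is None:
        kin = compute_kinematics(trial, align, config.filter_gyro)
    results = []
    for pair, e in angles.items():
        if rom_test:
            if test_id in (TestId.CRF, TestId.FSTS, TestId.PLS):
                met = rom_functional(e, test_id, config=config)
            else:
                met = rom_self_paced(e, test_id, config=config)
        else:
            met = MotionMetrics(test_id, pair)
        if fast and kin is not None and pair in kin.velocity:
            expected = conv.EXPECTED_REPS[test_id]
            v = kin.velocity[pair][:, conv.AXIS_ROW[axis]]
            a = kin.acceleration[pair][:, conv.AXIS_ROW[axis]]
            try:
                vp = extract_rep_peaks(v, expected, "both",
                                       config.velocity_prominence)
                met.vel_mean = trimmed_mean_abs([x for _, x in vp],
                                                config.trim_fraction)
                ap = extract_rep_peaks(a, expected, "both",
                                       prominence=0.2 * np.max(np.abs(a)))
                met.acc_mean = trimmed_mean_abs([x for _, x in ap],
                                                config.trim_fraction)
            except NoRepsDetected:
                met.flags.append("no_reps")
        met.flags = sorted(set(met.flags
                               + flag_unexpected_movement(met, e, test_id,
                                                          config)))
        if met.flags and rom_test:
            _reroute_integrated(trial, align, met, e, test_id, axis, config)
        results.append(met)
    return results


def _reroute_integrated(trial, align, met: MotionMetrics, e: EulerSeries,
                        test_id: TestId, axis: str,
                        config: MetricsConfig) -> None:
    """Replace orientation-based ROM with the gyroscope-integrated one."""
    try:
        theta = integrated_angle_series(trial, align, met.pair, axis)
    except StreamError:
        met.flags.append("integration_failed")
        return
    theta = lowpass_zero_phase(theta, fs=e.fs)
    m = conv.report_sign(test_id, met.pair)
    if met.directions:
        met.rom_dir1 = m * float(np.max(theta))
        met.rom_dir2 = m * float(np.min(theta))
        met.rom_total = float(np.max(theta) - np.min(theta))
    if met.rom_mean is not None:
        try:
            peaks = extract_rep_peaks(theta, conv.EXPECTED_REPS[test_id],
                                      "positive", config.angle_prominence)
            met.rom_mean = float(np.mean(np.abs([v for _, v in peaks])))
            met.n_reps = len(peaks)
        except NoRepsDetected:
            met.flags.append("integration_failed")
            return
    met.method = "integrated"
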