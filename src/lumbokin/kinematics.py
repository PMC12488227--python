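"""Relative segment rotations, Euler decomposition, unwrapping, filtering.

The processing chain for one segment pair is::

    quaternions -> rotation matrices -> relative rotation (four-factor
    product) -> neutral reference (first five samples) -> X-Z-Y Euler
    decomposition -> unwrap -> zero-phase low-pass filter

Angle semantics (see :mod:`lumbokin.conventions`): ``alpha`` axial rotation
about the longitudinal X axis, ``gamma`` lateral bend about the
anteroposterior Z axis, ``beta`` flexion/extension about the mediolateral
Y axis, with ``R = Rx(alpha) . Rz(gamma) . Ry(beta)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from . import conventions as conv
from .errors import StreamError, TooShort
from .types import SegmentPair, SensorStream, TrialRecording

GIMBAL_LIMIT_DEG = 89.9  #: |gamma| beyond which the decomposition is flagged


# ------------------------------------------------------------ rotations


def quat_to_rotation(q: np.ndarray) -> np.ndarray:
    """Convert scalar-first unit quaternion(s) to rotation matrices.

    Accepts shape ``(4,)`` or ``(n, 4)``; returns ``(3, 3)`` or ``(n, 3, 3)``.
    Quaternions within 1e-3 of unit norm are renormalized; a zero
    quaternion raises ``ValueError``.
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q2 = np.atleast_2d(q)
    norms = np.linalg.norm(q2, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero quaternion")
    q2 = q2 / norms[:, None]
    mats = Rotation.from_quat(q2[:, [1, 2, 3, 0]]).as_matrix()
    return mats[0] if single else mats


def _rx(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    c, s = np.cos(a), np.sin(a)
    out = np.zeros(a.shape + (3, 3))
    out[..., 0, 0] = 1
    out[..., 1, 1] = c
    out[..., 1, 2] = -s
    out[..., 2, 1] = s
    out[..., 2, 2] = c
    return out


def _ry(b: np.ndarray) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    c, s = np.cos(b), np.sin(b)
    out = np.zeros(b.shape + (3, 3))
    out[..., 1, 1] = 1
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def _rz(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    c, s = np.cos(g), np.sin(g)
    out = np.zeros(g.shape + (3, 3))
    out[..., 2, 2] = 1
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    return out


def compose_xzy(alpha_deg, gamma_deg, beta_deg) -> np.ndarray:
    """Build ``R = Rx(alpha) . Rz(gamma) . Ry(beta)`` from angles in degrees.

    Vectorized: scalar angles give ``(3, 3)``, arrays give ``(n, 3, 3)``.
    """
    a = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    g = np.deg2rad(np.asarray(gamma_deg, dtype=float))
    b = np.deg2rad(np.asarray(beta_deg, dtype=float))
    return _rx(a) @ _rz(g) @ _ry(b)


def decompose_xzy(R: np.ndarray, *, validate: bool = True
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Decompose rotation(s) as ``Rx(alpha) . Rz(gamma) . Ry(beta)``.

    Returns ``(alpha_deg, gamma_deg, beta_deg, gimbal_flag)`` with ``gamma``
    in [-90, 90] and ``alpha``, ``beta`` in (-180, 180].  Near the singular
    configuration (|gamma| > 89.9 deg) the flag is set and the remaining
    rotation is assigned to ``alpha`` (``beta`` forced to 0).

    In closed form, with ``M = Rx(a) Rz(g) Ry(b)``::

        M[0,1] = -sin g            M[2,1] = sin a cos g
        M[1,1] = cos a cos g       M[0,2] = cos g sin b
        M[0,0] = cos g cos b
    """
    R = np.asarray(R, dtype=float)
    single = R.ndim == 2
    M = R[None] if single else R
    if validate:
        err = np.abs(M @ np.swapaxes(M, -1, -2) - np.eye(3)).max()
        if err > 1e-3:
            raise ValueError(f"input not orthonormal (max deviation {err:.2e})")
    g = np.arcsin(np.clip(-M[:, 0, 1], -1.0, 1.0))
    gimbal = np.abs(np.rad2deg(g)) > GIMBAL_LIMIT_DEG
    a = np.arctan2(M[:, 2, 1], M[:, 1, 1])
    b = np.arctan2(M[:, 0, 2], M[:, 0, 0])
    if gimbal.any():
        # alpha-priority: set beta = 0, put the free rotation in alpha
        a = np.where(gimbal, np.arctan2(-M[:, 1, 2], M[:, 2, 2]), a)
        b = np.where(gimbal, 0.0, b)
    alpha, gamma, beta = np.rad2deg(a), np.rad2deg(g), np.rad2deg(b)
    if single:
        return float(alpha[0]), float(gamma[0]), float(beta[0]), bool(gimbal[0])
    return alpha, gamma, beta, gimbal


# --------------------------------------------------------------- series


@dataclass
class RotationSeries:
    """Per-sample 3x3 rotation matrices (sensor local -> global) for one sensor."""

    R: np.ndarray  # (n, 3, 3)
    fs: float

    def __len__(self) -> int:
        return len(self.R)


def rotation_series(stream: SensorStream) -> RotationSeries:
    """Rotation matrices from a stream's quaternion channel."""
    return RotationSeries(quat_to_rotation(stream.quat), stream.fs)


def relative_rotation_series(proximal: RotationSeries, distal: RotationSeries,
                             align, pair: SegmentPair) -> RotationSeries:
    """Four-factor relative rotation of the moving sensor in the reference
    anatomical frame::

        M(t) = A_ref . R_ref(t)^T . R_mov(t) . A_mov^T

    where ``A`` are the IMU-to-anatomical matrices from ``align`` and ``R``
    the sensor-to-global matrices from the quaternions.
    """
    if len(proximal) != len(distal):
        raise StreamError(
            f"{pair.label}: stream lengths differ ({len(proximal)} vs {len(distal)})")
    A_ref = align.matrices[pair.reference]
    A_mov = align.matrices[pair.moving]
    M = (A_ref @ np.swapaxes(proximal.R, -1, -2)) @ (distal.R @ A_mov.T)
    return RotationSeries(M, proximal.fs)


def neutral_reference(series: RotationSeries, n_neutral: int = 5) -> RotationSeries:
    """Reference every sample to the average of the first ``n_neutral`` rotations.

    The rotation average is the orthogonal polar factor (via SVD) of the
    element-wise mean; the output series starts at (near-)identity.
    """
    if len(series) < n_neutral:
        raise TooShort(f"need >= {n_neutral} samples, got {len(series)}")
    mean = series.R[:n_neutral].mean(axis=0)
    U, _, Vt = np.linalg.svd(mean)
    if np.linalg.det(U @ Vt) < 0:
        U[:, -1] *= -1.0
    R0 = U @ Vt
    return RotationSeries(R0.T @ series.R, series.fs)


def unwrap_series(angles_deg: np.ndarray, period: float = 360.0) -> np.ndarray:
    """Unwrap an angle series so consecutive jumps stay within ``period/2``."""
    return np.unwrap(np.asarray(angles_deg, dtype=float), period=period)


def lowpass_zero_phase(x: np.ndarray, fs: float = conv.FS_DEFAULT,
                       fc: float = conv.FC_DEFAULT,
                       order: int = conv.FILTER_ORDER) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward along axis 0).

    Defaults: third order, 5 Hz cutoff at 62.5 Hz sampling; the effective
    magnitude response is the squared one-pass response.
    """
    x = np.asarray(x, dtype=float)
    b, a = signal.butter(order, fc, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= padlen:
        raise TooShort(f"series of {x.shape[0]} samples too short to filter "
                       f"(needs > {padlen})")
    return signal.filtfilt(b, a, x, axis=0)


@dataclass
class EulerSeries:
    """Clinical Euler angle series for one segment pair (degrees)."""

    pair: SegmentPair
    alpha: np.ndarray          # axial rotation
    gamma: np.ndarray          # lateral bend
    beta: np.ndarray           # flexion/extension
    fs: float
    gimbal: np.ndarray = field(default=None)  # per-sample bool flags
    neutral_applied: bool = True

    def axis(self, name: str) -> np.ndarray:
        return {"alpha": self.alpha, "gamma": self.gamma, "beta": self.beta}[name]

    def __len__(self) -> int:
        return len(self.alpha)

    @property
    def gimbal_fraction(self) -> float:
        if self.gimbal is None or len(self.gimbal) == 0:
            return 0.0
        return float(np.mean(self.gimbal))


def euler_from_rotation_series(series: RotationSeries, pair: SegmentPair,
                               filter_angles: bool = True) -> EulerSeries:
    """Decompose, unwrap and (optionally) filter a relative rotation series."""
    alpha, gamma, beta, gimbal = decompose_xzy(series.R, validate=False)
    alpha = unwrap_series(alpha)
    beta = unwrap_series(beta)
    # gamma is range-limited to [-90, 90]; no wrap possible
    if filter_angles:
        stacked = lowpass_zero_phase(np.column_stack([alpha, gamma, beta]),
                                     fs=series.fs)
        alpha, gamma, beta = stacked[:, 0], stacked[:, 1], stacked[:, 2]
    return EulerSeries(pair, alpha, gamma, beta, series.fs, gimbal)


def compute_segment_angles(trial: TrialRecording, align,
                           filter_angles: bool = True
                           ) -> tuple[dict[SegmentPair, EulerSeries], dict]:
    """Full angle chain for every segment pair available in ``trial``.

    Order: relative rotation -> neutral reference -> decompose -> unwrap ->
    filter.  Returns ``(angles, omitted)`` where ``omitted`` maps skipped
    pairs to a reason string (missing sensor stream or alignment matrix).
    """
    angles: dict[SegmentPair, EulerSeries] = {}
    omitted: dict[SegmentPair, str] = {}
    rot_cache = {s: rotation_series(st) for s, st in trial.streams.items()}
    for pair in SegmentPair:
        missing = [s.value for s in (pair.reference, pair.moving)
                   if s not in trial.streams]
        if missing:
            omitted[pair] = f"missing stream(s): {', '.join(missing)}"
            continue
        unaligned = [s.value for s in (pair.reference, pair.moving)
                     if s not in align.matrices]
        if unaligned:
            omitted[pair] = f"missing alignment: {', '.join(unaligned)}"
            continue
        rel = relative_rotation_series(rot_cache[pair.reference],
                                       rot_cache[pair.moving], align, pair)
        rel = neutral_reference(rel)
        angles[pair] = euler_from_rotation_series(rel, pair, filter_angles)
    return angles, omitted
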