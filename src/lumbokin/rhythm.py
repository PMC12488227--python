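"""Lumbopelvic rhythm: phase segmentation and quartile lumbar:hip ratios.

For the self-paced flexion/extension test, the neutral-to-flexion and
neutral-to-extension phases are segmented automatically (the field's
traditional approach is manual selection); within each phase the onset is
delayed until hip excursion reaches 1 degree — which also guarantees the
ratio denominator never collapses — and the end is placed at 98% of the
maximum excursion of whichever region (lumbar or hip) peaks later.  The
window is split into four equal-duration quartiles and the per-sample
ratio |lumbar excursion| / max(|hip excursion|, 1 deg) is averaged within
each.  Excursions are measured from the neutral phase start; a ratio
above one means the lumbar region contributes more than the hip.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DegeneratePhase, HipStationary, NoPhases, TooShort

ONSET_HIP_DEG = 1.0       #: hip excursion starting the LPR window
END_FRACTION = 0.98       #: fraction of the later region's max ending it
PHASE_THRESHOLD_DEG = 2.0  #: departure from neutral starting a phase
PHASE_PROMINENCE = 5.0    #: apex prominence, deg


@dataclass
class FePhase:
    """One movement phase: neutral to the flexion or extension apex."""

    label: str   # "flexion" | "extension"
    start: int   # neutral departure sample
    end: int     # apex sample


@dataclass
class LprProfile:
    """Quartile ratios and window provenance for both phases."""

    flexion_q: list[float] | None = None
    extension_q: list[float] | None = None
    onset: dict[str, int] = field(default_factory=dict)
    end: dict[str, int] = field(default_factory=dict)
    phases: list[FePhase] = field(default_factory=list)


def detect_fe_phases(lumbar_beta: np.ndarray, hip_beta: np.ndarray,
                     threshold: float = PHASE_THRESHOLD_DEG,
                     prominence: float = PHASE_PROMINENCE) -> list[FePhase]:
    """Locate neutral-to-flexion / neutral-to-extension phases.

    Works on the summed trunk-direction signal (lumbar + hip sagittal
    angles, flexion positive).  Each phase runs from the last crossing of
    ``threshold`` away from neutral to the following apex.  Phases are
    returned in temporal order; ``NoPhases`` if the trial is static.
    """
    s = np.asarray(lumbar_beta, dtype=float) + np.asarray(hip_beta,
                                                          dtype=float)
    phases: list[FePhase] = []
    for sign, label in ((+1.0, "flexion"), (-1.0, "extension")):
        apexes, _ = signal.find_peaks(sign * s, prominence=prominence,
                                      height=threshold)
        for apex in apexes:
            below = np.flatnonzero(sign * s[:apex] < threshold)
            start = int(below[-1]) + 1 if below.size else 0
            phases.append(FePhase(label, start, int(apex)))
    if not phases:
        raise NoPhases("no flexion or extension apex found")
    phases.sort(key=lambda p: p.start)
    return phases


def lpr_window(lumbar_beta: np.ndarray, hip_beta: np.ndarray,
               phase: FePhase, onset_deg: float = ONSET_HIP_DEG,
               end_fraction: float = END_FRACTION) -> tuple[int, int]:
    """Onset and end samples of the rhythm window within a phase.

    Onset: first sample with |hip excursion from the phase start| >= 1 deg.
    End: first sample at which the later-peaking of the two regions reaches
    98% of its own maximum excursion.
    """
    sl = slice(phase.start, phase.end + 1)
    exc_l = np.abs(lumbar_beta[sl] - lumbar_beta[phase.start])
    exc_h = np.abs(hip_beta[sl] - hip_beta[phase.start])
    hits = np.flatnonzero(exc_h >= onset_deg)
    if not hits.size:
        raise HipStationary(
            f"hip excursion peaked at {exc_h.max():.2f} deg < {onset_deg}")
    onset = phase.start + int(hits[0])
    later = exc_l if int(np.argmax(exc_l)) >= int(np.argmax(exc_h)) else exc_h
    reach = np.flatnonzero(later >= end_fraction * later.max())
    end = phase.start + int(reach[0])
    if end <= onset:
        raise DegeneratePhase(f"window collapsed (onset {onset}, end {end})")
    return onset, end


def quartile_lpr_ratios(lumbar_beta: np.ndarray, hip_beta: np.ndarray,
                        onset: int, end: int, start: int | None = None,
                        guard_deg: float = 1.0,
                        incremental: bool = False) -> list[float]:
    """Mean lumbar:hip ratio in four equal-duration quartiles of
    ``[onset, end]``.

    ``start`` is the neutral reference sample for excursions (defaults to
    ``onset``); the pipeline passes the phase start so that, by the onset
    rule, the hip excursion — and hence the denominator — is at least the
    1-degree guard throughout the window.  ``incremental=True`` switches to
    per-sample excursion increments instead of cumulative excursion.
    """
    if end - onset + 1 < 8:
        raise TooShort("LPR window shorter than 8 samples")
    ref = onset if start is None else start
    lum = np.asarray(lumbar_beta, dtype=float)
    hip = np.asarray(hip_beta, dtype=float)
    if incremental:
        num = np.abs(np.diff(lum[onset:end + 1], prepend=lum[ref]))
        den = np.abs(np.diff(hip[onset:end + 1], prepend=hip[ref]))
    else:
        num = np.abs(lum[onset:end + 1] - lum[ref])
        den = np.abs(hip[onset:end + 1] - hip[ref])
    ratio = num / np.maximum(den, guard_deg)
    quartiles = np.array_split(ratio, 4)
    return [float(q.mean()) for q in quartiles]


def compute_lpr(lumbar_beta: np.ndarray, hip_beta: np.ndarray,
                **kwargs) -> LprProfile:
    """Full rhythm profile of a self-paced F/E trial.

    Uses the first flexion and first extension phase found; per phase the
    window rules above apply and excursions are referenced to the phase
    start.
    """
    phases = detect_fe_phases(lumbar_beta, hip_beta)
    profile = LprProfile(phases=phases)
    for phase in phases:
        if ((phase.label == "flexion" and profile.flexion_q is not None)
                or (phase.label == "extension"
                    and profile.extension_q is not None)):
            continue
        onset, end = lpr_window(lumbar_beta, hip_beta, phase)
        ratios = quartile_lpr_ratios(lumbar_beta, hip_beta, onset, end,
                                     start=phase.start, **kwargs)
        profile.onset[phase.label] = onset
        profile.end[phase.label] = end
        if phase.label == "flexion":
            profile.flexion_q = ratios
        else:
            profile.extension_q = ratios
    return profile
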