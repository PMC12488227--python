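"""Exception hierarchy for the lumbokin pipeline.

Every stage raises a specific subclass of :class:`LumbokinError` so callers
(e.g. the cohort pipeline) can log and skip a bad trial without masking
programming errors.
"""


class LumbokinError(Exception):
    """Base class for all pipeline errors."""


class ParseError(LumbokinError):
    """Trial file does not conform to the trial schema."""


class StreamError(LumbokinError):
    """Sensor stream violates an invariant (time order, quaternion norm, length)."""


class NoStompFound(LumbokinError):
    """No accelerometer sample exceeded the stomp threshold."""


class DegenerateWindow(LumbokinError):
    """Accelerometer window unusable for gravity estimation (near free-fall)."""


class AxisNotDominant(LumbokinError):
    """Gyroscope window has no dominant rotation axis."""


class DegenerateAxes(LumbokinError):
    """Vertical and horizontal axis candidates are near-parallel."""


class TooShort(LumbokinError):
    """Series shorter than the operation requires."""


class NoRepsDetected(LumbokinError):
    """Peak extraction found no repetitions."""


class NoPhases(LumbokinError):
    """No flexion/extension phase found in a self-paced F/E trial."""


class HipStationary(LumbokinError):
    """Hip excursion never reached the 1-degree onset threshold."""


class DegeneratePhase(LumbokinError):
    """Lumbopelvic-rhythm window collapsed (end not after onset)."""


class DegenerateSample(LumbokinError):
    """Statistic undefined on a constant or too-small sample."""


class AccountingError(LumbokinError):
    """Participant accounting produced a negative count."""


class EmptyCohort(LumbokinError):
    """No readable trials in the cohort directory."""
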