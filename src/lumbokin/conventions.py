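"""Axis semantics, per-test sign maps, and processing defaults.

Anatomical axis semantics (declared once; the alignment choreography
constructs frames with exactly these axes):

* **X** — longitudinal (superior). Rotation about X is axial rotation,
  angle ``alpha``; a left turn is positive.
* **Y** — mediolateral, oriented so flexion is positive. Rotation about Y
  is flexion/extension, angle ``beta``; forward flexion is positive.
* **Z = X x Y** — anteroposterior (posterior for an upright subject).
  Rotation about Z is lateral bending, angle ``gamma``; a left bend is
  positive.

The Euler decomposition order is ``R = Rx(alpha) . Rz(gamma) . Ry(beta)``
(sagittal/frontal/transverse clinical order).

Internally every pair uses the convention above. The clinical tables are
reported with per-test sign maps (one config table, below): axial rotation
and flexion/extension are sign-flipped for spinal pairs (left / flexion
negative), lateral bending is not, and the hip pair always carries the
opposite multiplier of the spinal pairs.
"""
from __future__ import annotations

from .types import SegmentPair, TestId

# ---------------------------------------------------------------- filtering
FS_DEFAULT = 62.5      #: Hz, nominal sensor rate
FC_DEFAULT = 5.0       #: Hz, low-pass cutoff
FILTER_ORDER = 3       #: Butterworth order (applied forward-backward)

# ----------------------------------------------------------------- axes
#: Euler angle name -> row index of the anatomical frame matrix
#: (rows are [X longitudinal; Y mediolateral; Z anteroposterior])
AXIS_ROW = {"alpha": 0, "beta": 1, "gamma": 2}

#: primary (cued) axis of each movement test
PRIMARY_AXIS: dict[TestId, str] = {
    TestId.AR_SELF: "alpha",
    TestId.AR_FAST: "alpha",
    TestId.LB_SELF: "gamma",
    TestId.LB_FAST: "gamma",
    TestId.FE_SELF: "beta",
    TestId.FLEX_FAST: "beta",
    TestId.CRF: "beta",
    TestId.FSTS: "beta",
    TestId.PLS: "beta",
}

#: movement family of each test, used by the sign maps and bounds table
TEST_FAMILY: dict[TestId, str] = {
    TestId.AR_SELF: "AR", TestId.AR_FAST: "AR",
    TestId.LB_SELF: "LB", TestId.LB_FAST: "LB",
    TestId.FE_SELF: "FE", TestId.FLEX_FAST: "FE",
    TestId.CRF: "SAG", TestId.FSTS: "SAG", TestId.PLS: "SAG",
}

#: bilateral self-paced tests report (left, right); F/E reports (flexion, extension)
DIRECTION_LABELS: dict[str, tuple[str, str]] = {
    "AR": ("left", "right"),
    "LB": ("left", "right"),
    "FE": ("flexion", "extension"),
    "SAG": ("flexion", "extension"),
}

#: reporting sign multiplier applied to the internal angle series,
#: keyed by (family, "spinal"|"hip").  Encodes the clinical table
#: conventions: AR left negative (spinal), LB left positive (spinal),
#: spinal flexion negative / hip flexion positive; hip flipped vs spinal
#: in every family.
_SPINAL_SIGN = {"AR": -1.0, "LB": +1.0, "FE": -1.0, "SAG": -1.0}
REPORT_SIGN: dict[tuple[str, str], float] = {}
for _fam, _s in _SPINAL_SIGN.items():
    REPORT_SIGN[(_fam, "spinal")] = _s
    REPORT_SIGN[(_fam, "hip")] = -_s


def pair_group(pair: SegmentPair) -> str:
    """"hip" for the hip/L5 pair, "spinal" otherwise."""
    return "hip" if pair is SegmentPair.HIP else "spinal"


def report_sign(test_id: TestId, pair: SegmentPair) -> float:
    """Sign multiplier taking the internal angle to the reported convention."""
    return REPORT_SIGN[(TEST_FAMILY[test_id], pair_group(pair))]


#: expected repetition counts per test (reps per direction for bilateral)
EXPECTED_REPS: dict[TestId, int] = {
    TestId.AR_SELF: 1, TestId.LB_SELF: 1, TestId.FE_SELF: 1,
    TestId.AR_FAST: 3, TestId.LB_FAST: 3, TestId.FLEX_FAST: 3,
    TestId.CRF: 3, TestId.FSTS: 5, TestId.PLS: 4,
}

#: time ceiling for the lifting test, seconds
PLS_TIME_CEILING = 20.0
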