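"""Cohort aggregation: median/IQR tables, strata, normality flags,
participant accounting, and the end-to-end directory pipeline.

Statistics are medians and interquartile ranges (linear interpolation
between order statistics), reported overall and stratified by biological
sex (male, female — other categories kept in the totals only) and by age
(>= 60 vs < 60 years).  The Kolmogorov–Smirnov normality result is a flag
only; it never switches the reported statistics.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import conventions as conv
from .alignment import align_trial
from .errors import (AccountingError, DegenerateSample, EmptyCohort,
                     LumbokinError)
from .io import read_trial
from .kinematics import compute_segment_angles
from .metrics import MetricsConfig, analyze_trial
from .rhythm import compute_lpr
from .types import SegmentPair, TestId

AGE_CUT = 60.0  #: years, default age stratification boundary

logger = logging.getLogger("lumbokin")


# ------------------------------------------------------------ statistics


def summarize_metric(values: np.ndarray, sex: np.ndarray | None = None,
                     age: np.ndarray | None = None,
                     age_cut: float = AGE_CUT) -> pd.DataFrame:
    """Median and quartiles of one metric, overall and per stratum.

    Returns rows keyed by ``stratum`` in {total, male, female, age>=60,
    age<60} with columns ``n, median, q1, q3``; an empty stratum gets
    ``n = 0`` and missing statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    strata: dict[str, np.ndarray] = {"total": np.ones(values.size, bool)}
    if sex is not None:
        sex = np.asarray(sex)
        strata["male"] = sex == "male"
        strata["female"] = sex == "female"
    if age is not None:
        age = np.asarray(age, dtype=float)
        strata[f"age>={age_cut:.0f}"] = age >= age_cut
        strata[f"age<{age_cut:.0f}"] = age < age_cut
    rows = []
    for name, mask in strata.items():
        v = values[mask]
        v = v[~np.isnan(v)]
        if v.size == 0:
            rows.append({"stratum": name, "n": 0, "median": math.nan,
                         "q1": math.nan, "q3": math.nan})
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        rows.append({"stratum": name, "n": int(v.size), "median": float(med),
                     "q1": float(q1), "q3": float(q3)})
    return pd.DataFrame(rows)


def normality_flag(values: np.ndarray,
                   alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-sample Kolmogorov–Smirnov test against a normal with the
    sample's own moments; ``normal`` is True when p > alpha.

    Raises ``DegenerateSample`` for n < 8 or a constant sample.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 8:
        raise DegenerateSample(f"need n >= 8, got {v.size}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateSample("constant sample")
    stat, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(stat), float(p), bool(p > alpha)


def account_participants(enrolled: int, exclusion_counts,
                         unusable: int) -> tuple[int, int]:
    """Usable-count arithmetic: returns (usable, total_excluded).

    usable = enrolled - sum(exclusions) - unusable; negative intermediate
    results raise ``AccountingError``.
    """
    exclusions = [int(c) for c in exclusion_counts]
    if enrolled < 0 or unusable < 0 or any(c < 0 for c in exclusions):
        raise AccountingError("counts must be non-negative")
    total_excluded = sum(exclusions)
    usable = enrolled - total_excluded - unusable
    if usable < 0:
        raise AccountingError(
            f"exclusions ({total_excluded}) + unusable ({unusable}) exceed "
            f"enrolled ({enrolled})")
    return usable, total_excluded


def cohort_tables(metrics: pd.DataFrame, age_cut: float = AGE_CUT
                  ) -> pd.DataFrame:
    """Median/IQR table rows for every (test, pair, metric) in a tidy
    metrics frame with participant_id, sex, age, test_id, pair, metric,
    value columns."""
    out = []
    for (test_id, pair, metric), grp in metrics.groupby(
            ["test_id", "pair", "metric"], sort=True):
        tbl = summarize_metric(grp["value"].to_numpy(),
                               grp["sex"].to_numpy() if "sex" in grp else None,
                               grp["age"].to_numpy() if "age" in grp else None,
                               age_cut)
        tbl.insert(0, "metric", metric)
        tbl.insert(0, "pair", pair)
        tbl.insert(0, "test_id", test_id)
        try:
            _, _, normal = normality_flag(grp["value"].to_numpy())
        except DegenerateSample:
            normal = None
        tbl["normal"] = normal
        out.append(tbl)
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------- pipeline


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    lpr: pd.DataFrame
    tables: pd.DataFrame
    log: list[str]


def run_pipeline(trial_dir: str | Path, config: MetricsConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Process a directory of trial files into metric, rhythm and cohort CSVs.

    Files are named ``<participant>_<TEST>.jsonl``; each participant needs
    a SYNC recording for alignment.  Per-trial failures are logged and the
    trial skipped — never fatal; ``EmptyCohort`` only if nothing was
    processed.
    """
    config = config or MetricsConfig()
    trial_dir = Path(trial_dir)
    files = sorted(trial_dir.glob("*.jsonl"))
    by_participant: dict[str, dict[TestId, Path]] = {}
    log: list[str] = []
    for path in files:
        stem = path.stem
        test_id = next((t for t in TestId if stem.endswith("_" + t.value)),
                       None)
        if test_id is None:
            log.append(f"SKIP {path.name}: unrecognized file name")
            continue
        pid = stem[: -len(test_id.value) - 1]
        by_participant.setdefault(pid, {})[test_id] = path

    metric_rows: list[dict] = []
    lpr_rows: list[dict] = []
    n_processed = 0
    for pid, tests in sorted(by_participant.items()):
        if TestId.SYNC not in tests:
            log.append(f"SKIP {pid}: no SYNC recording")
            continue
        try:
            sync = read_trial(tests[TestId.SYNC])
            align = align_trial(sync)
        except (LumbokinError, OSError) as exc:
            log.append(f"SKIP {pid}: alignment failed ({exc})")
            continue
        for test_id, path in sorted(tests.items(), key=lambda kv: kv[0].value):
            if test_id is TestId.SYNC:
                continue
            try:
                trial = read_trial(path)
                angles, omitted = compute_segment_angles(trial, align)
                for pair, reason in omitted.items():
                    log.append(f"{pid}/{test_id.value}: {pair.label} "
                               f"omitted ({reason})")
                for met in analyze_trial(trial, align, angles, config=config):
                    for row in met.rows(pid):
                        row.update(sex=trial.sex.value, age=trial.age)
                        metric_rows.append(row)
                if (test_id is TestId.FE_SELF
                        and SegmentPair.LUMBAR in angles
                        and SegmentPair.HIP in angles):
                    profile = compute_lpr(angles[SegmentPair.LUMBAR].beta,
                                          angles[SegmentPair.HIP].beta)
                    fs = angles[SegmentPair.LUMBAR].fs
                    for label, ratios in (("flexion", profile.flexion_q),
                                          ("extension",
                                           profile.extension_q)):
                        if ratios is None:
                            continue
                        for q, r in enumerate(ratios, start=1):
                            lpr_rows.append({
                                "participant_id": pid, "phase": label,
                                "quartile": q, "ratio": r,
                                "onset_t": profile.onset[label] / fs,
                                "end_t": profile.end[label] / fs,
                                "sex": trial.sex.value, "age": trial.age})
                n_processed += 1
            except (LumbokinError, OSError, ValueError) as exc:
                log.append(f"SKIP {pid}/{test_id.value}: "
                           f"{type(exc).__name__}: {exc}")
    if n_processed == 0:
        raise EmptyCohort(f"no processable trials under {trial_dir}")

    metrics = pd.DataFrame(metric_rows)
    lpr = pd.DataFrame(lpr_rows)
    tables = cohort_tables(metrics) if len(metrics) else pd.DataFrame()
    for line in log:
        logger.info(line)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        lpr.to_csv(out_dir / "lpr.csv", index=False)
        tables.to_csv(out_dir / "cohort_tables.csv", index=False)
        (out_dir / "pipeline.log").write_text("\n".join(log) + "\n")
    return PipelineResult(metrics, lpr, tables, log)
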