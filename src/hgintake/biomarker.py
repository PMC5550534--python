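"""Longitudinal blood and hair mercury biomarker summaries.

Blood Hg (μg/l) is measured at four timepoints of the intervention:
T1 (day 1, baseline), T2 (end of week 1), T3 (day 10, end of consumption)
and T4 (one month after). Hair Hg (μg/g) is measured at T1 and T4 only,
since hair integrates exposure with a lag.

The hair-to-blood ratio follows the study's unit convention — hair in μg/g
over blood in μg/l — which yields values near 0.23. (With matched mass
units, i.e. blood in μg/kg, the same data give the conventional ratio of
roughly 250:1; the numeric convention here simply omits the factor 1000
between litres of blood and grams of hair.) Ratios pair hair at T4 with
blood at T3: the end-of-study blood level is what the post-study hair
growth records. The module is purely descriptive — it ships no hypothesis
tests.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._stats import describe, sample_sd

TIMEPOINTS = ("T1", "T2", "T3", "T4")
MATRICES = ("blood", "hair")
#: hair is collected only at baseline and one month post-study
HAIR_TIMEPOINTS = ("T1", "T4")


@dataclass(frozen=True)
class BiomarkerRecord:
    """One measurement: blood in μg/l or hair in μg/g at one timepoint."""

    subject_id: str
    timepoint: str
    matrix: str
    value: float

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, "
                             f"got {self.timepoint!r}")
        if self.matrix not in MATRICES:
            raise ValueError(f"matrix must be one of {MATRICES}, got {self.matrix!r}")
        if self.matrix == "hair" and self.timepoint not in HAIR_TIMEPOINTS:
            raise ValueError(f"hair is only collected at {HAIR_TIMEPOINTS}, "
                             f"got {self.timepoint}")
        if self.value < 0:
            raise ValueError(f"negative biomarker value {self.value}")


@dataclass(frozen=True)
class LinearFit:
    """OLS line through paired blood (x) and hair (y) values."""

    slope: float
    intercept: float
    r: float
    n: int


def timepoint_summary(records: Sequence[BiomarkerRecord], matrix: str,
                      timepoint: str,
                      group_by: Mapping[str, object] | None = None,
                      ) -> dict:
    """{n, mean, sd} for one matrix/timepoint, optionally per covariate group.

    ``group_by`` maps subject_id to a group label (e.g. smoker status or
    amalgam presence); when given, a dict of per-label summaries is
    returned. Grouped output is descriptive only.
    """
    matching = [r for r in records
                if r.matrix == matrix and r.timepoint == timepoint]
    if not matching:
        raise ValueError(f"no records for matrix {matrix!r} at {timepoint}")

    def _summary(vals: list[float]) -> dict[str, float]:
        return {"n": len(vals), "mean": float(np.mean(vals)),
                "sd": sample_sd(vals)}

    if group_by is None:
        return _summary([r.value for r in matching])
    groups: dict[object, list[float]] = {}
    for r in matching:
        groups.setdefault(group_by.get(r.subject_id), []).append(r.value)
    return {label: _summary(vals) for label, vals in groups.items()}


def hair_blood_ratio(hair: float, blood: float) -> float:
    """Hair-to-blood Hg ratio, (μg/g) / (μg/l), per the study convention."""
    if blood <= 0:
        raise ValueError(f"blood concentration must be positive, got {blood}")
    if hair < 0:
        raise ValueError(f"negative hair concentration {hair}")
    return hair / blood


def paired_hair_blood(records: Sequence[BiomarkerRecord],
                      hair_timepoint: str = "T4",
                      blood_timepoint: str = "T3",
                      ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-subject (blood, hair) pairs for the ratio and the linear fit.

    Default pairing is hair at T4 against blood at T3. Subjects missing
    either measurement are dropped.
    """
    blood = {r.subject_id: r.value for r in records
             if r.matrix == "blood" and r.timepoint == blood_timepoint}
    hair = {r.subject_id: r.value for r in records
            if r.matrix == "hair" and r.timepoint == hair_timepoint}
    ids = sorted(set(blood) & set(hair))
    return (ids,
            np.array([blood[i] for i in ids], dtype=float),
            np.array([hair[i] for i in ids], dtype=float))


def ratio_summary(records: Sequence[BiomarkerRecord],
                  hair_timepoint: str = "T4",
                  blood_timepoint: str = "T3", *,
                  ratio_of_means: bool = False) -> dict[str, float]:
    """Distribution of per-subject hair/blood ratios.

    The headline statistic is the mean of per-subject ratios; set
    ``ratio_of_means=True`` to get the alternative reading (ratio of the
    two population means) as ``mean`` with no distribution.
    """
    ids, blood, hair = paired_hair_blood(records, hair_timepoint, blood_timepoint)
    if not ids:
        raise ValueError("no subjects with both hair and blood measurements")
    if ratio_of_means:
        return {"n": len(ids),
                "mean": hair_blood_ratio(float(hair.mean()), float(blood.mean()))}
    ratios = [hair_blood_ratio(h, b) for h, b in zip(hair, blood)]
    return describe(ratios)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares of hair (y) on blood (x) with Pearson r.

    A constant response (zero variance in y) leaves Pearson's r undefined;
    it is reported as 0.0, consistent with "no linear association".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    r = 0.0 if np.ptp(y) == 0 else float(res.rvalue)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r=r, n=int(x.size))
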