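"""Domain containers: exams, strain curves, cohort records, risk intervals.

The six mid-ventricular segments follow standard short-axis nomenclature:
mid-antero-septal (MAS), mid-infero-septal (MIS), mid-antero-lateral (MAL),
mid-infero-lateral (MIL), mid-anterior (MA) and mid-inferior (MI). Septal and
lateral segments carry the paradoxical-motion signal; the anterior and
inferior segments act as within-exam references.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    ChronologyError,
    InvalidMetadata,
    MalformedTrace,
    MissingSegment,
    ValidationError,
)


class Segment(str, enum.Enum):
    """The six mid-ventricular LV segments, in canonical output order."""

    MAS = "MAS"
    MIS = "MIS"
    MAL = "MAL"
    MIL = "MIL"
    MA = "MA"
    MI = "MI"

    @classmethod
    def ordered(cls) -> tuple["Segment", ...]:
        return (cls.MAS, cls.MIS, cls.MAL, cls.MIL, cls.MA, cls.MI)


#: Septal + lateral segments, whose strain pattern shifts with septal motion grade.
SEPTAL_LATERAL = (Segment.MAS, Segment.MIS, Segment.MAL, Segment.MIL)
#: Reference segments that keep a normal pattern at every grade.
REFERENCE_SEGMENTS = (Segment.MA, Segment.MI)
#: The eight pairwise contrasts reported for time-to-peak and partial AUC.
DIFFERENCE_PAIRS = tuple(
    (a, b) for a in SEPTAL_LATERAL for b in REFERENCE_SEGMENTS
)

MIN_SAMPLES = 8


@dataclass(frozen=True)
class SegmentCurve:
    """One segment's radial strain trace over a single cardiac cycle."""

    segment: Segment
    time_ms: np.ndarray
    strain_pct: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_ms, dtype=float)
        s = np.asarray(self.strain_pct, dtype=float)
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "strain_pct", s)
        if t.ndim != 1 or s.ndim != 1 or len(t) != len(s):
            raise MalformedTrace(
                f"segment {self.segment.value}: time and strain must be 1-D "
                f"and equal length (got {len(t)} vs {len(s)})"
            )
        if len(t) < MIN_SAMPLES:
            raise MalformedTrace(
                f"segment {self.segment.value}: need >= {MIN_SAMPLES} samples, got {len(t)}"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(s)):
            raise MalformedTrace(f"segment {self.segment.value}: non-finite samples")
        if t[0] < 0:
            raise MalformedTrace(f"segment {self.segment.value}: time starts before 0")
        if np.any(np.diff(t) <= 0):
            raise MalformedTrace(
                f"segment {self.segment.value}: time not strictly increasing"
            )


@dataclass(frozen=True)
class ExamStrain:
    """Six segment traces plus cycle metadata for one echocardiographic exam."""

    exam_id: str
    patient_id: str
    cycle_length_ms: float
    avc_time_ms: float
    curves: dict[Segment, SegmentCurve]
    heart_rate_bpm: Optional[float] = None
    true_grade: Optional[int] = None  # ground truth, set only by the simulator

    def __post_init__(self):
        if self.cycle_length_ms <= 0:
            raise InvalidMetadata(f"exam {self.exam_id}: cycle_length_ms must be > 0")
        if not (0 < self.avc_time_ms < self.cycle_length_ms):
            raise InvalidMetadata(
                f"exam {self.exam_id}: AVC time {self.avc_time_ms} outside cycle "
                f"(0, {self.cycle_length_ms})"
            )
        present = set(self.curves)
        for seg in Segment:
            if seg not in present:
                raise MissingSegment(f"exam {self.exam_id}: missing segment {seg.value}")
        if len(self.curves) != 6:
            raise MissingSegment(f"exam {self.exam_id}: expected exactly 6 segments")
        for seg, curve in self.curves.items():
            if curve.segment != seg:
                raise MalformedTrace(
                    f"exam {self.exam_id}: curve keyed {seg.value} labelled "
                    f"{curve.segment.value}"
                )
            if curve.time_ms[-1] > self.cycle_length_ms + 1e-9:
                raise MalformedTrace(
                    f"exam {self.exam_id}, segment {seg.value}: last sample "
                    f"{curve.time_ms[-1]} ms beyond cycle {self.cycle_length_ms} ms"
                )
        if self.heart_rate_bpm is not None:
            implied = 60000.0 / self.cycle_length_ms
            if not math.isclose(self.heart_rate_bpm, implied, rel_tol=0.05):
                raise InvalidMetadata(
                    f"exam {self.exam_id}: heart rate {self.heart_rate_bpm} bpm "
                    f"inconsistent with cycle length (implies {implied:.1f} bpm)"
                )


class Outcome(str, enum.Enum):
    DIED = "died"
    DISCHARGED_ALIVE = "discharged_alive"
    CENSORED = "censored"


@dataclass(frozen=True)
class ExamRecord:
    """One cohort row: grades, RV/LV ratio, covariates and ICU outcome."""

    exam_id: str
    patient_id: str
    exam_day: float
    grade_2d: Optional[int]
    grade_combined: Optional[int]
    rv_lv_ratio: Optional[float]
    age_years: float
    saps2: int
    cardiomyopathy: bool
    outcome: Outcome
    outcome_day: float

    def __post_init__(self):
        for name, g in (("grade_2d", self.grade_2d), ("grade_combined", self.grade_combined)):
            if g is not None and g not in (0, 1, 2):
                raise ValidationError(
                    f"exam {self.exam_id}: {name}={g!r} outside {{0,1,2}}"
                )
        if self.exam_day < 0 or self.outcome_day < 0:
            raise ValidationError(f"exam {self.exam_id}: negative day")
        if self.exam_day > self.outcome_day:
            raise ChronologyError(
                f"exam {self.exam_id}: exam_day {self.exam_day} after outcome_day "
                f"{self.outcome_day}"
            )
        if self.rv_lv_ratio is not None and self.rv_lv_ratio < 0:
            raise ValidationError(f"exam {self.exam_id}: negative RV/LV ratio")
        if self.saps2 < 0:
            raise ValidationError(f"exam {self.exam_id}: negative SAPS II")


@dataclass(frozen=True)
class NormalizedExam:
    """An exam on normalized axes: time in % cycle, strain scaled to exam max 1."""

    exam_id: str
    time_pct: dict[Segment, np.ndarray]
    strain_norm: dict[Segment, np.ndarray]
    avc_pct: float

    def __post_init__(self):
        if not (0 < self.avc_pct < 100):
            raise InvalidMetadata(f"exam {self.exam_id}: avc_pct outside (0, 100)")
        global_max = max(float(np.max(v)) for v in self.strain_norm.values())
        if abs(global_max - 1.0) > 1e-9:
            raise InvalidMetadata(
                f"exam {self.exam_id}: normalized global max {global_max} != 1"
            )


@dataclass(frozen=True)
class SegmentFeatures:
    """Per-segment engineered metrics on the normalized exam.

    ttp_pct: time-to-peak in % of the cardiac cycle.
    ttp_minus_avc_pct: time-to-peak minus aortic valve closure, % cycle; a
        positive value marks post-systolic (paradoxical) peak strain.
    pauc: partial area under the normalized strain curve over the 33-66 %
        window, reported in arbitrary units (scaled, see features module).
    """

    segment: Segment
    ttp_pct: float
    ttp_minus_avc_pct: float
    pauc: float


@dataclass(frozen=True)
class DifferenceFeatures:
    """Pairwise septal/lateral-minus-reference contrasts plus AVC-relative timing."""

    exam_id: str
    d_ttp: dict[tuple[Segment, Segment], float]
    d_pauc: dict[tuple[Segment, Segment], float]
    ttp_minus_avc: dict[Segment, float]


@dataclass(frozen=True)
class RaterGrades:
    """Grades assigned to one exam by a fixed panel of raters."""

    exam_id: str
    grades: tuple[int, ...]

    def __post_init__(self):
        if len(self.grades) < 2:
            raise ValidationError(f"exam {self.exam_id}: need >= 2 raters")
        for g in self.grades:
            if g not in (0, 1, 2):
                raise ValidationError(f"exam {self.exam_id}: grade {g!r} outside {{0,1,2}}")


class ExposureState(str, enum.Enum):
    """RV-dilatation severity crossed with septal-motion grade.

    Moderate dilatation: RV/LV end-diastolic area ratio in [0.6, 1.0);
    severe: ratio >= 1.0. Grade 0 maps to NONE regardless of the ratio.
    """

    NONE = "none"
    MODERATE_GRADE1 = "moderate_grade1"
    MODERATE_GRADE2 = "moderate_grade2"
    SEVERE_GRADE1 = "severe_grade1"
    SEVERE_GRADE2 = "severe_grade2"

    @classmethod
    def exposure_levels(cls) -> tuple["ExposureState", ...]:
        """Non-reference levels, in model-report order."""
        return (
            cls.MODERATE_GRADE1,
            cls.MODERATE_GRADE2,
            cls.SEVERE_GRADE1,
            cls.SEVERE_GRADE2,
        )


@dataclass(frozen=True)
class RiskInterval:
    """One counting-process row (start, stop] with the state in force."""

    patient_id: str
    start_day: float
    stop_day: float
    state: ExposureState
    event: bool
    age_years: float
    saps2: int
    cardiomyopathy: bool

    def __post_init__(self):
        if not self.start_day < self.stop_day:
            raise ValidationError(
                f"patient {self.patient_id}: interval ({self.start_day}, "
                f"{self.stop_day}] is empty"
            )


@dataclass(frozen=True)
class CoxTerm:
    """One fitted model term: hazard ratio with Wald CI, or non-estimable."""

    name: str
    hr: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p: Optional[float]
    estimable: bool = True


@dataclass(frozen=True)
class CoxResult:
    """Fitted time-dependent Cox model summary."""

    terms: dict[str, CoxTerm]
    n_patients: int
    n_events: int
    tie_method: str = "efron"

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_events": self.n_events,
            "tie_method": self.tie_method,
            "terms": {
                k: {
                    "hr": t.hr,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p": t.p,
                    "estimable": t.estimable,
                }
                for k, t in self.terms.items()
            },
        }
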