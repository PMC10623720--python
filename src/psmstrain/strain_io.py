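"""Tidy strain-table and cohort-table readers/writers.

The canonical strain exchange format is a long CSV (UTF-8, '.' decimal, header
row) with one row per sample:

    exam_id, patient_id, segment, time_ms, strain_pct,
    cycle_length_ms, avc_time_ms [, heart_rate_bpm]

Per-exam metadata columns must be constant within an exam. A JSON mirror with
one object per exam is also accepted. Time stays in milliseconds from cycle
start at the I/O boundary; normalization to % cycle is a downstream transform.

The cohort table is a CSV with one row per exam carrying the visual grades,
the RV/LV end-diastolic area ratio, covariates and the ICU outcome. Missing
grades and ratios are preserved as missing, never imputed.
"""
from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    DuplicateExam,
    InvalidMetadata,
    MalformedTrace,
    MissingSegment,
    ValidationError,
)
from .types import ExamRecord, ExamStrain, Outcome, Segment, SegmentCurve

STRAIN_COLUMNS = [
    "exam_id",
    "patient_id",
    "segment",
    "time_ms",
    "strain_pct",
    "cycle_length_ms",
    "avc_time_ms",
]

COHORT_COLUMNS = [
    "exam_id",
    "patient_id",
    "exam_day",
    "grade_2d",
    "grade_combined",
    "rv_lv_ratio",
    "age_years",
    "saps2",
    "cardiomyopathy",
    "outcome",
    "outcome_day",
]

PathLike = Union[str, Path]


def _exam_from_group(exam_id: str, g: pd.DataFrame) -> ExamStrain:
    patient_ids = g["patient_id"].unique()
    if len(patient_ids) != 1:
        raise InvalidMetadata(f"exam {exam_id}: multiple patient_ids {list(patient_ids)}")
    for col in ("cycle_length_ms", "avc_time_ms"):
        if g[col].nunique() != 1:
            raise InvalidMetadata(f"exam {exam_id}: column {col} not constant within exam")
    cycle = float(g["cycle_length_ms"].iloc[0])
    avc = float(g["avc_time_ms"].iloc[0])
    hr: Optional[float] = None
    if "heart_rate_bpm" in g.columns:
        vals = g["heart_rate_bpm"].dropna().unique()
        if len(vals) > 1:
            raise InvalidMetadata(f"exam {exam_id}: heart_rate_bpm not constant")
        if len(vals) == 1:
            hr = float(vals[0])

    curves: dict[Segment, SegmentCurve] = {}
    for seg_label, sub in g.groupby("segment", sort=False):
        try:
            seg = Segment(seg_label)
        except ValueError:
            raise MalformedTrace(
                f"exam {exam_id}: unknown segment label {seg_label!r}"
            ) from None
        if seg in curves:
            raise DuplicateExam(f"exam {exam_id}: duplicate segment {seg.value}")
        sub = sub.sort_values("time_ms", kind="stable")
        curves[seg] = SegmentCurve(
            segment=seg,
            time_ms=sub["time_ms"].to_numpy(dtype=float),
            strain_pct=sub["strain_pct"].to_numpy(dtype=float),
        )
    for seg in Segment:
        if seg not in curves:
            raise MissingSegment(f"exam {exam_id}: missing segment {seg.value}")
    return ExamStrain(
        exam_id=str(exam_id),
        patient_id=str(patient_ids[0]),
        cycle_length_ms=cycle,
        avc_time_ms=avc,
        curves=curves,
        heart_rate_bpm=hr,
    )


def read_strain_table(path: PathLike, dialect: str = "csv") -> list[ExamStrain]:
    """Parse a tidy strain table into validated exams.

    Row order in the file is irrelevant: samples are sorted by time within each
    segment and exams are returned sorted by exam_id. ``dialect`` selects
    ``"csv"`` (canonical long format) or ``"json"`` (one object per exam).
    """
    path = Path(path)
    if dialect == "json":
        return _read_strain_json(path)
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in STRAIN_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidMetadata(f"{path}: missing columns {missing}")
    exams = [
        _exam_from_group(exam_id, g)
        for exam_id, g in df.groupby("exam_id", sort=True)
    ]
    return exams


def _read_strain_json(path: Path) -> list[ExamStrain]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    exams = []
    for obj in payload:
        curves = {}
        for seg_label, trace in obj["curves"].items():
            seg = Segment(seg_label)
            curves[seg] = SegmentCurve(
                segment=seg,
                time_ms=np.asarray(trace["time_ms"], dtype=float),
                strain_pct=np.asarray(trace["strain_pct"], dtype=float),
            )
        exams.append(
            ExamStrain(
                exam_id=obj["exam_id"],
                patient_id=obj["patient_id"],
                cycle_length_ms=float(obj["cycle_length_ms"]),
                avc_time_ms=float(obj["avc_time_ms"]),
                curves=curves,
                heart_rate_bpm=obj.get("heart_rate_bpm"),
            )
        )
    return sorted(exams, key=lambda e: e.exam_id)


def strain_frame(exams: Iterable[ExamStrain]) -> pd.DataFrame:
    """Long-format DataFrame of the exams, in deterministic row order."""
    rows = []
    for exam in sorted(exams, key=lambda e: e.exam_id):
        for seg in Segment.ordered():
            curve = exam.curves[seg]
            n = len(curve.time_ms)
            rows.append(
                pd.DataFrame(
                    {
                        "exam_id": exam.exam_id,
                        "patient_id": exam.patient_id,
                        "segment": seg.value,
                        "time_ms": curve.time_ms,
                        "strain_pct": curve.strain_pct,
                        "cycle_length_ms": exam.cycle_length_ms,
                        "avc_time_ms": exam.avc_time_ms,
                        "heart_rate_bpm": np.full(n, np.nan)
                        if exam.heart_rate_bpm is None
                        else np.full(n, exam.heart_rate_bpm),
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=STRAIN_COLUMNS + ["heart_rate_bpm"])
    return pd.concat(rows, ignore_index=True)


def write_strain_table(exams: Iterable[ExamStrain], path: PathLike) -> None:
    """Write exams as the canonical long CSV (rows grouped by exam, then segment)."""
    strain_frame(exams).to_csv(path, index=False)


def _opt_int(v) -> Optional[int]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    f = float(v)
    if not f.is_integer():
        raise ValidationError(f"grade {v!r} is not an integer")
    return int(f)


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer, float)):
        return bool(int(v))
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean {v!r}")


def read_cohort_table(path: PathLike) -> list[ExamRecord]:
    """Parse the cohort CSV into validated exam records.

    Missing grades and RV/LV ratios are kept as ``None``; duplicate
    (patient_id, exam_day) pairs are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    records = []
    seen: set[tuple[str, float]] = set()
    for _, row in df.iterrows():
        key = (str(row["patient_id"]), float(row["exam_day"]))
        if key in seen:
            raise DuplicateExam(
                f"duplicate exam for patient {key[0]} on day {key[1]}"
            )
        seen.add(key)
        records.append(
            ExamRecord(
                exam_id=str(row["exam_id"]),
                patient_id=str(row["patient_id"]),
                exam_day=float(row["exam_day"]),
                grade_2d=_opt_int(row["grade_2d"]),
                grade_combined=_opt_int(row["grade_combined"]),
                rv_lv_ratio=_opt_float(row["rv_lv_ratio"]),
                age_years=float(row["age_years"]),
                saps2=int(row["saps2"]),
                cardiomyopathy=_parse_bool(row["cardiomyopathy"]),
                outcome=Outcome(str(row["outcome"])),
                outcome_day=float(row["outcome_day"]),
            )
        )
    return records


def cohort_frame(records: Sequence[ExamRecord]) -> pd.DataFrame:
    """Records as a DataFrame with missing values as NaN."""
    return pd.DataFrame(
        {
            "exam_id": [r.exam_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "exam_day": [r.exam_day for r in records],
            "grade_2d": [np.nan if r.grade_2d is None else r.grade_2d for r in records],
            "grade_combined": [
                np.nan if r.grade_combined is None else r.grade_combined for r in records
            ],
            "rv_lv_ratio": [
                np.nan if r.rv_lv_ratio is None else r.rv_lv_ratio for r in records
            ],
            "age_years": [r.age_years for r in records],
            "saps2": [r.saps2 for r in records],
            "cardiomyopathy": [r.cardiomyopathy for r in records],
            "outcome": [r.outcome.value for r in records],
            "outcome_day": [r.outcome_day for r in records],
        }
    )


def write_cohort_table(records: Sequence[ExamRecord], path: PathLike) -> None:
    cohort_frame(records).to_csv(path, index=False)
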