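"""Feature engineering on radial strain curves.

The pipeline mirrors standard segmental strain analysis of paradoxical septal
motion (PSM):

1. *Normalize* each exam: time is re-expressed as a percentage of the cardiac
   cycle, and every strain value is divided by the single exam-wide maximum,
   so curves from exams with different heart rates and strain amplitudes are
   comparable. The normalizer is per-exam (not per-segment) so inter-segment
   amplitude contrasts survive normalization.
2. *Time-to-peak* (ttp): the % of the cycle at which a segment reaches its
   maximal strain. A septal peak after aortic valve closure (AVC) marks
   post-systolic contraction, the strain signature of PSM.
3. *Partial AUC* (pauc): the area under the normalized strain curve over the
   33-66 % window of the cycle, where PSM most alters the curve shape.
4. *Differences*: septal/lateral-minus-reference contrasts of ttp and pauc,
   plus per-segment ttp minus AVC, remove between-patient offsets.

All features are computed on curves resampled to a common 101-point uniform
grid over [0, 100] % of the cycle (1 %-cycle resolution).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateExam, MissingSegment, WindowOutOfRange
from .types import (
    DIFFERENCE_PAIRS,
    REFERENCE_SEGMENTS,
    SEPTAL_LATERAL,
    DifferenceFeatures,
    ExamStrain,
    NormalizedExam,
    Segment,
    SegmentFeatures,
)

#: Number of points of the internal uniform resampling grid (1 %-cycle steps).
GRID_POINTS = 101
#: Partial-AUC window bounds, % of the cardiac cycle.
PAUC_WINDOW = (33.0, 66.0)
#: Output scale for pauc: the unit integral over the full cycle maps to this
#: many arbitrary units, putting pauc differences on the order of hundreds.
PAUC_SCALE = 1000.0


def normalize_exam(exam: ExamStrain) -> NormalizedExam:
    """Map an exam onto normalized axes (% cycle, exam-max strain = 1).

    Raises :class:`DegenerateExam` when no strictly positive strain sample
    exists, since the max-normalizer is then undefined.
    """
    global_max = max(float(np.max(c.strain_pct)) for c in exam.curves.values())
    if global_max <= 0:
        raise DegenerateExam(
            f"exam {exam.exam_id}: no strictly positive strain sample"
        )
    scale = 100.0 / exam.cycle_length_ms
    time_pct = {seg: c.time_ms * scale for seg, c in exam.curves.items()}
    strain_norm = {seg: c.strain_pct / global_max for seg, c in exam.curves.items()}
    return NormalizedExam(
        exam_id=exam.exam_id,
        time_pct=time_pct,
        strain_norm=strain_norm,
        avc_pct=exam.avc_time_ms * scale,
    )


def resample_curve(
    time_pct: np.ndarray, strain: np.ndarray, n_points: int = GRID_POINTS
) -> tuple[np.ndarray, np.ndarray]:
    """Linear resampling onto the uniform [0, 100] % grid.

    Outside the sampled range the edge values are held constant (the first and
    last strain samples), which only matters for curves not sampled over the
    full cycle.
    """
    grid = np.linspace(0.0, 100.0, n_points)
    return grid, np.interp(grid, time_pct, strain)


def moving_average(strain: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average used as optional pre-peak-detection smoothing."""
    if width <= 1:
        return strain
    kernel = np.ones(width) / width
    # reflect-pad so the ends are averaged over real samples only
    pad = width // 2
    padded = np.pad(strain, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(strain)]
    return out


def time_to_peak(time_pct: np.ndarray, strain: np.ndarray) -> float:
    """Time of the global strain maximum in % cycle (earliest sample on ties)."""
    idx = int(np.argmax(strain))
    return float(time_pct[idx])


def partial_auc(
    time_pct: np.ndarray,
    strain: np.ndarray,
    lo: float = PAUC_WINDOW[0],
    hi: float = PAUC_WINDOW[1],
) -> float:
    """Trapezoidal integral of the curve over ``time_pct`` in [lo, hi].

    Window edges falling between samples are handled by linear interpolation,
    so the value is independent of whether a sample lies exactly on the bound.
    A constant curve of value 1 integrates to ``hi - lo``.
    """
    if not (0.0 <= lo < hi <= 100.0):
        raise WindowOutOfRange(f"window [{lo}, {hi}] must satisfy 0 <= lo < hi <= 100")
    t = np.asarray(time_pct, dtype=float)
    v = np.asarray(strain, dtype=float)
    eps = 1e-9
    if lo < t[0] - eps or hi > t[-1] + eps:
        raise WindowOutOfRange(
            f"window [{lo}, {hi}] outside sampled range [{t[0]}, {t[-1]}]"
        )
    inner = (t > lo) & (t < hi)
    knots = np.concatenate(([lo], t[inner], [hi]))
    values = np.interp(knots, t, v)
    return float(np.trapezoid(values, knots))


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs for the feature pipeline.

    pauc_lo/pauc_hi: integration window in % cycle.
    pauc_scale: arbitrary-unit scale for pauc (unit full-cycle integral ->
        ``pauc_scale`` units).
    smooth_width: moving-average width in grid samples before peak detection;
        1 disables smoothing (the default: peaks are taken on the raw grid).
    """

    pauc_lo: float = PAUC_WINDOW[0]
    pauc_hi: float = PAUC_WINDOW[1]
    pauc_scale: float = PAUC_SCALE
    smooth_width: int = 1
    n_grid: int = GRID_POINTS


def segment_features(
    exam: NormalizedExam, config: FeatureConfig = FeatureConfig()
) -> dict[Segment, SegmentFeatures]:
    """Per-segment ttp, ttp-AVC and pauc on the resampled normalized exam."""
    out: dict[Segment, SegmentFeatures] = {}
    for seg in Segment.ordered():
        if seg not in exam.time_pct:
            raise MissingSegment(f"exam {exam.exam_id}: missing segment {seg.value}")
        grid, strain = resample_curve(
            exam.time_pct[seg], exam.strain_norm[seg], config.n_grid
        )
        smoothed = moving_average(strain, config.smooth_width)
        ttp = time_to_peak(grid, smoothed)
        pauc_raw = partial_auc(grid, strain, config.pauc_lo, config.pauc_hi)
        out[seg] = SegmentFeatures(
            segment=seg,
            ttp_pct=ttp,
            ttp_minus_avc_pct=ttp - exam.avc_pct,
            pauc=pauc_raw / 100.0 * config.pauc_scale,
        )
    return out


def difference_features(
    features: Mapping[Segment, SegmentFeatures], exam_id: str = ""
) -> DifferenceFeatures:
    """The eight septal/lateral-vs-reference contrasts for ttp and pauc.

    d_ttp[(a, b)] = ttp(a) - ttp(b) exactly, so reversing a pair negates the
    difference. Also carries the six per-segment ttp-minus-AVC values.
    """
    for seg in Segment:
        if seg not in features:
            raise MissingSegment(f"exam {exam_id}: missing features for {seg.value}")
    d_ttp = {}
    d_pauc = {}
    for a, b in DIFFERENCE_PAIRS:
        d_ttp[(a, b)] = features[a].ttp_pct - features[b].ttp_pct
        d_pauc[(a, b)] = features[a].pauc - features[b].pauc
    ttp_minus_avc = {seg: features[seg].ttp_minus_avc_pct for seg in Segment.ordered()}
    return DifferenceFeatures(
        exam_id=exam_id, d_ttp=d_ttp, d_pauc=d_pauc, ttp_minus_avc=ttp_minus_avc
    )


def exam_features(
    exam: ExamStrain, config: FeatureConfig = FeatureConfig()
) -> tuple[dict[Segment, SegmentFeatures], DifferenceFeatures]:
    """Full pipeline for one exam: normalize, per-segment features, contrasts."""
    norm = normalize_exam(exam)
    segs = segment_features(norm, config)
    return segs, difference_features(segs, exam_id=exam.exam_id)


@dataclass(frozen=True)
class HeuristicThresholds:
    """Cutoffs for the exploratory rule-based grade suggester (% cycle / a.u.).

    t2_avc: grade-2 requires the septal/lateral median post-AVC delay of the
        peak to exceed this many % cycle.
    t2_ttp: ... and the largest septal ttp contrast to exceed this.
    t1_ttp / t1_pauc: grade-1 requires the median septal ttp contrast or the
        median septal pauc contrast to exceed these.
    """

    t1_ttp: float = 0.5
    t2_ttp: float = 2.0
    t2_avc: float = 2.0
    t1_pauc: float = 50.0

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "HeuristicThresholds":
        return cls(**{k: float(v) for k, v in d.items()})


#: The four septal contrasts (MAS/MIS vs MA/MI) used by the grade heuristic.
SEPTAL_PAIRS = tuple(
    (a, b) for a in (Segment.MAS, Segment.MIS) for b in REFERENCE_SEGMENTS
)


def grade_heuristic(
    diff: DifferenceFeatures,
    thresholds: HeuristicThresholds = HeuristicThresholds(),
) -> tuple[int, str]:
    """Rule-based PSM grade suggestion from the difference features.

    Exploratory: the reference grading of septal motion is human visual
    consensus; this rule operationalizes the qualitative strain signatures
    (septal peak after AVC, septal peak later than reference segments, septal
    partial-AUC excess) with configurable cutoffs.

    Returns ``(grade, rationale)``.
    """
    for seg in Segment:
        if seg not in diff.ttp_minus_avc:
            raise MissingSegment(f"missing ttp_minus_avc for {seg.value}")
    sl_avc = float(np.median([diff.ttp_minus_avc[s] for s in SEPTAL_LATERAL]))
    septal_dttp = [diff.d_ttp[p] for p in SEPTAL_PAIRS]
    septal_dpauc = [diff.d_pauc[p] for p in SEPTAL_PAIRS]
    max_dttp = float(np.max(septal_dttp))
    med_dttp = float(np.median(septal_dttp))
    med_dpauc = float(np.median(septal_dpauc))

    if sl_avc > thresholds.t2_avc and max_dttp > thresholds.t2_ttp:
        return 2, (
            f"grade 2 (exploratory): septal/lateral median ttp-AVC {sl_avc:.1f} "
            f"> {thresholds.t2_avc} %cycle and max septal d_ttp {max_dttp:.1f} "
            f"> {thresholds.t2_ttp} %cycle"
        )
    if med_dttp > thresholds.t1_ttp or med_dpauc > thresholds.t1_pauc:
        return 1, (
            f"grade 1 (exploratory): median septal d_ttp {med_dttp:.1f} %cycle "
            f"or median septal d_pauc {med_dpauc:.0f} a.u. above thresholds "
            f"({thresholds.t1_ttp}, {thresholds.t1_pauc})"
        )
    return 0, (
        f"grade 0 (exploratory): no septal delay signature "
        f"(median d_ttp {med_dttp:.1f}, median d_pauc {med_dpauc:.0f}, "
        f"median ttp-AVC {sl_avc:.1f})"
    )


def _pair_name(pair: tuple[Segment, Segment]) -> str:
    return f"{pair[0].value}_{pair[1].value}"


def features_frame(
    exams: Iterable[ExamStrain], config: FeatureConfig = FeatureConfig()
) -> pd.DataFrame:
    """Wide per-exam feature table: 6x3 segment features + 16 differences."""
    rows = []
    for exam in exams:
        segs, diff = exam_features(exam, config)
        row: dict[str, object] = {"exam_id": exam.exam_id, "patient_id": exam.patient_id}
        if exam.true_grade is not None:
            row["true_grade"] = exam.true_grade
        for seg in Segment.ordered():
            f = segs[seg]
            row[f"ttp_{seg.value}"] = f.ttp_pct
            row[f"ttp_minus_avc_{seg.value}"] = f.ttp_minus_avc_pct
            row[f"pauc_{seg.value}"] = f.pauc
        for pair in DIFFERENCE_PAIRS:
            row[f"d_ttp_{_pair_name(pair)}"] = diff.d_ttp[pair]
            row[f"d_pauc_{_pair_name(pair)}"] = diff.d_pauc[pair]
        rows.append(row)
    return pd.DataFrame(rows)


#: Wide-table column names of the 16 difference metrics, in report order.
DIFFERENCE_COLUMNS = [f"d_pauc_{_pair_name(p)}" for p in DIFFERENCE_PAIRS] + [
    f"d_ttp_{_pair_name(p)}" for p in DIFFERENCE_PAIRS
]
#: Per-segment AVC-relative timing columns.
TTP_MINUS_AVC_COLUMNS = [f"ttp_minus_avc_{s.value}" for s in Segment.ordered()]
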