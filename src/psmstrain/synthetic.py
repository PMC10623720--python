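"""Seeded generators for strain waveforms, rater panels and longitudinal cohorts.

Waveforms
---------
Each segment is modelled as a raised-cosine systolic bump peaking shortly
before aortic valve closure (AVC). With paradoxical septal motion (grade >= 1)
the septal segments — mirrored by their opposite lateral segments — gain a
delayed post-systolic raised-cosine component whose peak sits at/just after
AVC at grade 1 and 3-11 % of the cycle after AVC at grade 2, with an amplitude
growing with severity. The anterior and inferior reference segments always
peak before AVC. This reproduces the qualitative strain signatures of septal
dyskinesia (delayed septal time-to-peak, septal peak after AVC, septal excess
of mid-cycle area under the curve) without claiming hemodynamic realism.

Raters
------
Two raters report the true grade with probability ``q`` and an adjacent grade
otherwise; ``q`` is calibrated by bisection against the analytic expected
Fleiss kappa so panels with any target agreement in reach can be produced.

Cohorts
-------
Patients undergo scheduled serial exams; the septal-motion grade evolves by a
Markov transition matrix, the RV/LV area ratio is drawn consistent with the
grade (grade 2 always implies severe RV dilatation, ratio >= 1.0), and death
and discharge compete as piecewise-exponential hazards, death modulated by the
current exposure state and baseline covariates. A 2D-only grading is derived
from the true (combined) grading by a downgrade-only error model, reflecting
that adding strain to visual reading reclassifies almost exclusively upward.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import CalibrationError, ConfigError, DomainError
from .types import (
    SEPTAL_LATERAL,
    ExamRecord,
    ExamStrain,
    ExposureState,
    Outcome,
    RaterGrades,
    Segment,
    SegmentCurve,
)

# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------


def _raised_cosine(t: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """Smooth unit bump: 0.5*(1+cos(pi*(t-c)/w)) on |t-c| <= w, else 0."""
    x = (t - center) / half_width
    out = np.where(np.abs(x) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return out


@dataclass(frozen=True)
class WaveformParams:
    """Shape and noise parameters of the simulated six-segment exam.

    Timing parameters are fractions of the cardiac cycle; amplitudes are in %
    radial strain. Defaults describe a ventilated patient in sinus rhythm:
    75 bpm, systole ending at 40 % of the cycle, segmental peak strain ~45 %
    just before AVC. ``noise_sd`` is additive white noise on the traces (the
    speckle-tracking output is heavily smoothed, hence a small default);
    ``timing_jitter_sd`` and ``amplitude_jitter_rel`` give between-segment
    biological variability; ``delay_sd`` varies the post-systolic delay
    between exams (severity heterogeneity within a grade).
    """

    heart_rate_bpm: float = 75.0
    avc_fraction: float = 0.40
    n_samples: int = 101
    base_peak_frac: float = 0.39
    base_width_frac: float = 0.18
    base_amplitude: float = 45.0
    delayed_width_frac: float = 0.10
    delayed_ratio_grade1: float = 1.15
    delayed_ratio_grade2: float = 1.5
    delay_grade1: float = 0.010
    delay_grade2: float = 0.045
    delay_sd: float = 0.012
    delay_clip_grade1: tuple[float, float] = (0.0, 0.03)
    delay_clip_grade2: tuple[float, float] = (0.03, 0.11)
    noise_sd: float = 0.5
    timing_jitter_sd: float = 0.005
    amplitude_jitter_rel: float = 0.10
    peak_time_frac: Optional[Mapping[Segment, float]] = None
    peak_amplitude: Optional[Mapping[Segment, float]] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0 < self.avc_fraction < 1) or not (0 < self.base_peak_frac < 1):
            raise ConfigError("cycle fractions must lie in (0, 1)")
        if self.n_samples < 8:
            raise ConfigError("n_samples must be >= 8")
        if self.base_amplitude < 0 or self.noise_sd < 0:
            raise ConfigError("amplitudes and noise must be >= 0")

    @classmethod
    def noiseless(cls, **overrides) -> "WaveformParams":
        """Archetype parameters: no noise, no jitter, mean delays."""
        base = dict(
            noise_sd=0.0,
            timing_jitter_sd=0.0,
            amplitude_jitter_rel=0.0,
            delay_sd=0.0,
        )
        base.update(overrides)
        return cls(**base)


def simulate_exam(
    grade: int,
    params: WaveformParams = WaveformParams(),
    rng: Optional[np.random.Generator] = None,
    exam_id: str = "sim-exam",
    patient_id: str = "sim-patient",
) -> ExamStrain:
    """One six-segment exam of the requested septal-motion grade.

    Fully reproducible given ``rng`` or ``params.seed``. The returned exam
    carries ``true_grade`` for recovery tests.
    """
    if grade not in (0, 1, 2):
        raise DomainError(f"grade must be 0, 1 or 2, got {grade!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cycle_ms = 60000.0 / params.heart_rate_bpm
    t = np.linspace(0.0, 1.0, params.n_samples)

    if grade == 1:
        ratio, delay_mean, clip = (
            params.delayed_ratio_grade1,
            params.delay_grade1,
            params.delay_clip_grade1,
        )
    elif grade == 2:
        ratio, delay_mean, clip = (
            params.delayed_ratio_grade2,
            params.delay_grade2,
            params.delay_clip_grade2,
        )
    else:
        ratio, delay_mean, clip = 0.0, 0.0, (0.0, 0.0)
    # one severity draw per exam; segments add small independent jitter
    exam_delay = float(np.clip(delay_mean + rng.normal(0.0, params.delay_sd), *clip)) \
        if grade else 0.0

    curves: dict[Segment, SegmentCurve] = {}
    for seg in Segment.ordered():
        amp = params.base_amplitude
        if params.peak_amplitude and seg in params.peak_amplitude:
            amp = float(params.peak_amplitude[seg])
        amp *= max(0.2, 1.0 + rng.normal(0.0, params.amplitude_jitter_rel))
        c_base = params.base_peak_frac + rng.normal(0.0, params.timing_jitter_sd)
        strain = amp * _raised_cosine(t, c_base, params.base_width_frac)
        if grade >= 1 and seg in SEPTAL_LATERAL:
            c_del = (
                params.avc_fraction
                + exam_delay
                + rng.normal(0.0, params.timing_jitter_sd)
            )
            if params.peak_time_frac and seg in params.peak_time_frac:
                c_del = float(params.peak_time_frac[seg])
            strain = strain + amp * ratio * _raised_cosine(
                t, c_del, params.delayed_width_frac
            )
        elif params.peak_time_frac and seg in params.peak_time_frac:
            strain = amp * _raised_cosine(
                t, float(params.peak_time_frac[seg]), params.base_width_frac
            )
        if params.noise_sd > 0:
            strain = strain + rng.normal(0.0, params.noise_sd, size=len(t))
        curves[seg] = SegmentCurve(
            segment=seg, time_ms=t * cycle_ms, strain_pct=strain
        )
    return ExamStrain(
        exam_id=exam_id,
        patient_id=patient_id,
        cycle_length_ms=cycle_ms,
        avc_time_ms=params.avc_fraction * cycle_ms,
        curves=curves,
        heart_rate_bpm=params.heart_rate_bpm,
        true_grade=grade,
    )


def simulate_exam_set(
    n_per_grade: int,
    params: WaveformParams = WaveformParams(),
    seed: int = 0,
) -> list[ExamStrain]:
    """``n_per_grade`` exams of each grade, deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    exams = []
    for grade in (0, 1, 2):
        for i in range(n_per_grade):
            exams.append(
                simulate_exam(
                    grade,
                    params,
                    rng=rng,
                    exam_id=f"sim-g{grade}-{i:04d}",
                    patient_id=f"simpat-g{grade}-{i:04d}",
                )
            )
    return exams


def simulate_cohort_strain(
    records: Sequence["ExamRecord"],
    params: WaveformParams = WaveformParams(),
    seed: int = 0,
) -> list[ExamStrain]:
    """One strain exam per cohort record, graded by its combined grade."""
    rng = np.random.default_rng(seed)
    exams = []
    for rec in records:
        if rec.grade_combined is None:
            continue
        exams.append(
            simulate_exam(
                rec.grade_combined,
                params,
                rng=rng,
                exam_id=rec.exam_id,
                patient_id=rec.patient_id,
            )
        )
    return exams


# ---------------------------------------------------------------------------
# Raters
# ---------------------------------------------------------------------------


def _rater_confusion(q: float) -> np.ndarray:
    """p(report j | true g): correct w.p. q, else an adjacent grade."""
    return np.array(
        [
            [q, 1 - q, 0.0],
            [(1 - q) / 2, q, (1 - q) / 2],
            [0.0, 1 - q, q],
        ]
    )


def expected_fleiss_kappa(true_grades: Sequence[int], q: float) -> float:
    """Analytic expected two-rater Fleiss kappa under the adjacent-error model."""
    counts = np.bincount(np.asarray(true_grades, dtype=int), minlength=3)
    pi = counts / counts.sum()
    conf = _rater_confusion(q)
    p_o = float(np.sum(pi[:, None] * conf**2))
    marg = pi @ conf
    p_e = float(np.sum(marg**2))
    if 1.0 - p_e < 1e-12:
        raise CalibrationError("expected agreement 1: kappa undefined for these grades")
    return (p_o - p_e) / (1.0 - p_e)


def calibrate_rater_accuracy(
    true_grades: Sequence[int], kappa_target: float, tol: float = 1e-10
) -> float:
    """Bisection for the per-rater accuracy q achieving the target kappa."""
    if not (0 < kappa_target <= 1):
        raise DomainError("kappa_target must lie in (0, 1]")
    lo, hi = 1.0 / 3.0, 1.0
    k_lo = expected_fleiss_kappa(true_grades, lo)
    k_hi = expected_fleiss_kappa(true_grades, hi)
    if kappa_target > k_hi + 1e-12 or kappa_target < k_lo - 1e-12:
        raise CalibrationError(
            f"kappa {kappa_target} unattainable (range [{k_lo:.3f}, {k_hi:.3f}] "
            "for these grade marginals)"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected_fleiss_kappa(true_grades, mid) < kappa_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def simulate_raters(
    true_grades: Sequence[int],
    kappa_target: float,
    seed: int = 0,
    exam_ids: Optional[Sequence[str]] = None,
) -> list[RaterGrades]:
    """Two-rater panel whose expected Fleiss kappa matches ``kappa_target``."""
    grades = np.asarray(true_grades, dtype=int)
    if exam_ids is None:
        exam_ids = [f"exam-{i:04d}" for i in range(len(grades))]
    q = calibrate_rater_accuracy(grades, kappa_target)
    rng = np.random.default_rng(seed)
    conf = _rater_confusion(q)
    out = []
    for eid, g in zip(exam_ids, grades):
        r1 = int(rng.choice(3, p=conf[g]))
        r2 = int(rng.choice(3, p=conf[g]))
        out.append(RaterGrades(exam_id=str(eid), grades=(r1, r2)))
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_DEFAULT_TRANSITIONS = (
    (0.75, 0.18, 0.07),
    (0.15, 0.60, 0.25),
    (0.05, 0.20, 0.75),
)
#: Cross-sectional grade mix of a ventilated ARDS cohort (roughly half normal
#: septal motion, one third transient flattening, the rest sustained/inverted).
_DEFAULT_INITIAL = (0.52, 0.33, 0.15)

_DEFAULT_STATE_LOG_HR = {
    ExposureState.NONE: 0.0,
    ExposureState.MODERATE_GRADE1: math.log(1.2),
    ExposureState.MODERATE_GRADE2: math.log(2.0),
    ExposureState.SEVERE_GRADE1: math.log(1.5),
    ExposureState.SEVERE_GRADE2: math.log(6.0),
}


@dataclass(frozen=True)
class CohortParams:
    """Longitudinal cohort generator settings.

    Hazards are per day; ``state_log_hr`` multiplies the baseline death hazard
    while the patient occupies each exposure state; discharge acts as an
    independent censoring hazard. ``downgrade_prob`` (one grade) and
    ``downgrade2_prob`` (grade 2 read as 0) define the 2D-only misreading of
    the true combined grade.
    """

    n_patients: int = 67
    exam_days: tuple[float, ...] = (0.0, 4.0, 8.0)
    transition_matrix: tuple[tuple[float, float, float], ...] = _DEFAULT_TRANSITIONS
    initial_grade_probs: tuple[float, float, float] = _DEFAULT_INITIAL
    baseline_hazard: float = 0.015
    discharge_hazard: float = 0.05
    max_follow_up: float = 60.0
    state_log_hr: Mapping[ExposureState, float] = field(
        default_factory=lambda: dict(_DEFAULT_STATE_LOG_HR)
    )
    age_log_hr: float = 0.02
    saps2_log_hr: float = 0.02
    cardiomyopathy_log_hr: float = 0.3
    downgrade_prob: float = 0.3
    downgrade2_prob: float = 0.17
    missing_ratio_prob: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        tm = np.asarray(self.transition_matrix, dtype=float)
        if tm.shape != (3, 3) or np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0):
            raise ConfigError("transition matrix rows must be nonneg and sum to 1")
        if abs(sum(self.initial_grade_probs) - 1.0) > 1e-9:
            raise ConfigError("initial grade probabilities must sum to 1")
        if self.baseline_hazard < 0 or self.discharge_hazard < 0:
            raise ConfigError("hazards must be >= 0")
        if len(self.exam_days) < 1 or self.exam_days[0] != 0.0:
            raise ConfigError("exam schedule must start at day 0")


def _draw_ratio(grade: int, rng: np.random.Generator) -> float:
    """RV/LV ratio consistent with the grade (grade 2 => severe dilatation)."""
    if grade == 0:
        return float(np.clip(rng.normal(0.70, 0.10), 0.30, 1.30))
    if grade == 1:
        return float(np.clip(rng.normal(0.80, 0.15), 0.60, 1.30))
    return float(np.clip(rng.normal(1.10, 0.10), 1.00, 1.50))


def _state_of(grade: int, ratio: float) -> ExposureState:
    if grade == 0 or ratio < 0.6:
        return ExposureState.NONE
    severe = ratio >= 1.0
    if grade == 1:
        return ExposureState.SEVERE_GRADE1 if severe else ExposureState.MODERATE_GRADE1
    return ExposureState.SEVERE_GRADE2 if severe else ExposureState.MODERATE_GRADE2


def _downgrade(grade: int, rng: np.random.Generator, p1: float, p2: float) -> int:
    if grade == 0:
        return 0
    u = rng.random()
    if grade == 2:
        if u < p2:
            return 0
        if u < p2 + p1:
            return 1
        return 2
    return 0 if u < p1 else 1


def simulate_cohort(
    params: CohortParams = CohortParams(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[ExamRecord], dict]:
    """Serial exam records plus ground truth for recovery tests.

    Returns ``(records, truth)`` where ``truth`` holds per-patient true state
    timelines and the generating parameters. Grades evolve by the transition
    matrix at scheduled exams; between exams the death hazard is piecewise
    constant at the current state's level; discharge competes as censoring.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    tm = np.asarray(params.transition_matrix, dtype=float)
    records: list[ExamRecord] = []
    truth_patients = []
    days = list(params.exam_days)
    for i in range(params.n_patients):
        pid = f"pt-{i:04d}"
        age = float(np.clip(rng.normal(67.0, 8.0), 30.0, 90.0))
        saps2 = int(np.clip(round(rng.normal(35.0, 8.0)), 6, 80))
        cmp_hist = bool(rng.random() < 0.12)
        cov_lp = (
            params.age_log_hr * (age - 67.0)
            + params.saps2_log_hr * (saps2 - 35.0)
            + params.cardiomyopathy_log_hr * cmp_hist
        )

        grades = [int(rng.choice(3, p=params.initial_grade_probs))]
        for _ in days[1:]:
            grades.append(int(rng.choice(3, p=tm[grades[-1]])))
        ratios = [_draw_ratio(g, rng) for g in grades]
        states = [_state_of(g, r) for g, r in zip(grades, ratios)]

        # competing piecewise-exponential death/discharge from day 0
        boundaries = days[1:] + [params.max_follow_up]
        t_now, outcome, outcome_day = 0.0, Outcome.CENSORED, params.max_follow_up
        for k, t_next in enumerate(boundaries):
            lam_d = params.baseline_hazard * math.exp(
                params.state_log_hr[states[k]] + cov_lp
            )
            lam_c = params.discharge_hazard
            t_death = rng.exponential(1.0 / lam_d) if lam_d > 0 else math.inf
            t_disch = rng.exponential(1.0 / lam_c) if lam_c > 0 else math.inf
            t_event = min(t_death, t_disch)
            if t_now + t_event < t_next:
                outcome_day = t_now + t_event
                outcome = Outcome.DIED if t_death <= t_disch else Outcome.DISCHARGED_ALIVE
                break
            t_now = t_next
        if outcome_day <= 0:
            outcome_day = 1e-3  # guard: event numerically at inclusion

        exam_rows = []
        for day, g, ratio in zip(days, grades, ratios):
            if day > outcome_day:
                break
            if day == outcome_day:
                break  # an exam at the outcome instant adds no information
            g2d = _downgrade(g, rng, params.downgrade_prob, params.downgrade2_prob)
            r = None if rng.random() < params.missing_ratio_prob else ratio
            rec = ExamRecord(
                exam_id=f"{pid}-d{int(day)}",
                patient_id=pid,
                exam_day=day,
                grade_2d=g2d,
                grade_combined=g,
                rv_lv_ratio=r,
                age_years=age,
                saps2=saps2,
                cardiomyopathy=cmp_hist,
                outcome=outcome,
                outcome_day=outcome_day,
            )
            exam_rows.append(rec)
        records.extend(exam_rows)
        truth_patients.append(
            {
                "patient_id": pid,
                "grades": grades[: len(exam_rows)],
                "states": [s.value for s in states[: len(exam_rows)]],
                "outcome": outcome.value,
                "outcome_day": outcome_day,
            }
        )
    truth = {
        "state_log_hr": {s.value: v for s, v in params.state_log_hr.items()},
        "baseline_hazard": params.baseline_hazard,
        "patients": truth_patients,
    }
    return records, truth
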