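"""Exposure states, counting-process construction and the Cox fit."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from psmstrain.errors import ChronologyError, MissingValue, NoEvents
from psmstrain.survival import (
    assign_state,
    build_intervals,
    cohort_intervals,
    fit_td_cox,
    intervals_frame,
)
from psmstrain.synthetic import CohortParams, simulate_cohort
from psmstrain.types import ExposureState, Outcome, RiskInterval


# ---------------------------------------------------------------------------
# State assignment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ratio,grade,expected",
    [
        (1.10, 2, ExposureState.SEVERE_GRADE2),
        (0.59, 0, ExposureState.NONE),
        (1.0, 1, ExposureState.SEVERE_GRADE1),
        (0.8, 1, ExposureState.MODERATE_GRADE1),
        (0.95, 2, ExposureState.MODERATE_GRADE2),
        (2.0, 0, ExposureState.NONE),  # grade 0 -> none regardless of ratio
    ],
)
def test_assign_state_thresholds(record_factory, ratio, grade, expected):
    rec = record_factory(rv_lv_ratio=ratio, grade_combined=grade)
    assert assign_state(rec, "grade_combined") == expected


def test_assign_state_missing_and_inconsistent(record_factory):
    with pytest.raises(MissingValue):
        assign_state(record_factory(grade_combined=None), "grade_combined")
    with pytest.raises(MissingValue):
        assign_state(record_factory(grade_combined=1, rv_lv_ratio=None))
    # a graded septal-motion abnormality without RV dilatation is inconsistent
    with pytest.raises(MissingValue):
        assign_state(record_factory(grade_combined=1, rv_lv_ratio=0.5))


# ---------------------------------------------------------------------------
# Interval construction
# ---------------------------------------------------------------------------

def test_single_exam_death(record_factory):
    rec = record_factory(
        grade_combined=0, outcome=Outcome.DIED, outcome_day=10.0
    )
    (iv,) = build_intervals([rec])
    assert (iv.start_day, iv.stop_day) == (0.0, 10.0)
    assert iv.state == ExposureState.NONE and iv.event


def test_two_interval_construction(record_factory):
    recs = [
        record_factory(exam_id="e1", exam_day=0.0, grade_combined=0,
                       outcome=Outcome.DISCHARGED_ALIVE, outcome_day=12.0),
        record_factory(exam_id="e2", exam_day=4.0, grade_combined=2,
                       rv_lv_ratio=1.2, outcome=Outcome.DISCHARGED_ALIVE,
                       outcome_day=12.0),
    ]
    ivs = build_intervals(recs)
    assert [(iv.start_day, iv.stop_day, iv.state, iv.event) for iv in ivs] == [
        (0.0, 4.0, ExposureState.NONE, False),
        (4.0, 12.0, ExposureState.SEVERE_GRADE2, False),
    ]


def test_duplicate_exam_submission_is_idempotent(record_factory):
    recs = [
        record_factory(exam_id="e1", exam_day=0.0, grade_combined=1, rv_lv_ratio=0.8,
                       outcome=Outcome.DIED, outcome_day=9.0),
        record_factory(exam_id="e2", exam_day=3.0, grade_combined=2, rv_lv_ratio=1.1,
                       outcome=Outcome.DIED, outcome_day=9.0),
    ]
    once = build_intervals(recs)
    twice = build_intervals(recs + recs)
    assert once == twice


def test_unusable_first_exam_defers_entry(record_factory):
    recs = [
        record_factory(exam_id="e1", exam_day=0.0, grade_combined=1, rv_lv_ratio=None,
                       outcome=Outcome.DIED, outcome_day=8.0),
        record_factory(exam_id="e2", exam_day=4.0, grade_combined=1, rv_lv_ratio=0.8,
                       outcome=Outcome.DIED, outcome_day=8.0),
    ]
    ivs = build_intervals(recs)
    assert ivs[0].start_day == 4.0  # enters at the first usable exam


def test_exam_after_outcome_rejected(record_factory):
    with pytest.raises(ChronologyError):
        build_intervals(
            [
                record_factory(exam_id="e1", exam_day=0.0, outcome_day=5.0),
                record_factory(exam_id="e2", exam_day=6.0, outcome_day=6.0),
            ]
        )


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_interval_lengths_conserve_follow_up(seed):
    """Per patient, interval lengths sum to outcome_day minus entry day."""
    records, _ = simulate_cohort(CohortParams(n_patients=20, seed=seed))
    by_patient = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    for pid, recs in by_patient.items():
        try:
            ivs = build_intervals(recs)
        except MissingValue:
            continue
        total = sum(iv.stop_day - iv.start_day for iv in ivs)
        expected = recs[0].outcome_day - ivs[0].start_day
        assert total == pytest.approx(expected)
        assert ivs[0].start_day == 0.0  # generator always yields a usable day-0 exam
        # contiguity and single terminal event
        for a, b in zip(ivs, ivs[1:]):
            assert a.stop_day == b.start_day
        assert all(not iv.event for iv in ivs[:-1])


# ---------------------------------------------------------------------------
# Cox fit
# ---------------------------------------------------------------------------

def _toy_intervals():
    """3 subjects, 2 events, one binary covariate (cardiomyopathy)."""
    mk = lambda pid, stop, event, x: RiskInterval(
        patient_id=pid, start_day=0.0, stop_day=stop, state=ExposureState.NONE,
        event=event, age_years=0.0, saps2=0, cardiomyopathy=x,
    )
    return [mk("a", 1.0, True, True), mk("b", 3.0, False, True), mk("c", 2.0, True, False)]


def test_cox_matches_closed_form_score_root():
    """Coefficient equals the analytic root of the partial-likelihood score."""
    res = fit_td_cox(_toy_intervals(), covariates=("cardiomyopathy",))
    # score: 1 - 2e^b/(2e^b+1) - e^b/(e^b+1) = 0
    def score(b):
        eb = np.exp(b)
        return 1.0 - 2 * eb / (2 * eb + 1.0) - eb / (eb + 1.0)

    beta_oracle = brentq(score, -5.0, 5.0, xtol=1e-12)
    assert abs(np.log(res.terms["cardiomyopathy"].hr) - beta_oracle) < 1e-6


def test_no_events_raises(record_factory):
    ivs = [
        RiskInterval("a", 0.0, 5.0, ExposureState.NONE, False, 60.0, 30, False)
    ]
    with pytest.raises(NoEvents):
        fit_td_cox(ivs)


def _time_fixed_newton_step(X, times, events, beta):
    """Newton step of the tie-free time-fixed Cox partial likelihood at beta."""
    score = np.zeros(len(beta))
    hess = np.zeros((len(beta), len(beta)))
    eta = X @ beta
    w = np.exp(eta)
    for i in np.flatnonzero(events):
        at_risk = times >= times[i]
        wr = w[at_risk]
        xr = X[at_risk]
        denom = wr.sum()
        xbar = (wr[:, None] * xr).sum(axis=0) / denom
        score += X[i] - xbar
        xc = xr - xbar
        hess -= (wr[:, None, None] * (xc[:, :, None] * xc[:, None, :])).sum(axis=0) / denom
    return np.linalg.solve(hess, score)


def test_single_exam_equals_time_fixed_cox():
    """With one exam per patient the fit is the time-fixed Cox MLE.

    Certified by evaluating the hand-coded time-fixed partial-likelihood score
    at the time-varying estimate: the Newton correction must be below 1e-8.
    Event days are continuous, so there are no ties and Efron equals the plain
    partial likelihood.
    """
    records, _ = simulate_cohort(
        CohortParams(n_patients=150, exam_days=(0.0,), seed=21)
    )
    ivs = cohort_intervals(records, "grade_combined")
    res = fit_td_cox(ivs, fit_options={"precision": 1e-12})
    df = intervals_frame(ivs)
    fit_cols = [c for c in df.columns if c.startswith("state_")
                if df[c].sum() > 0] + ["age_years", "saps2", "cardiomyopathy"]
    fit_cols = [c for c in fit_cols if df[c].nunique() > 1]
    # tie-free event times by construction (only censoring days coincide)
    assert df.loc[df["event"], "stop"].nunique() == int(df["event"].sum())
    beta = np.array(
        [np.log(res.terms[c.replace("state_", "")].hr) for c in fit_cols]
    )
    step = _time_fixed_newton_step(
        df[fit_cols].to_numpy(float),
        df["stop"].to_numpy(float),
        df["event"].to_numpy(bool),
        beta,
    )
    assert np.max(np.abs(step)) < 1e-8


def test_nonestimable_level_reported_not_crashed(record_factory):
    # severe_grade2 occupied but with zero events -> non-estimable, fit survives
    ivs = [
        RiskInterval("a", 0.0, 5.0, ExposureState.NONE, True, 60.0, 30, False),
        RiskInterval("b", 0.0, 6.0, ExposureState.NONE, True, 65.0, 40, True),
        RiskInterval("c", 0.0, 7.0, ExposureState.SEVERE_GRADE2, False, 70.0, 35, False),
        RiskInterval("d", 0.0, 8.0, ExposureState.NONE, False, 55.0, 25, False),
    ]
    res = fit_td_cox(ivs, covariates=("age_years",))
    assert not res.terms["severe_grade2"].estimable
    assert res.n_events == 2
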