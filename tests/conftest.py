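import numpy as np
import pytest

from psmstrain.synthetic import WaveformParams, simulate_exam
from psmstrain.types import ExamRecord, Outcome, Segment


@pytest.fixture
def noiseless_params() -> WaveformParams:
    return WaveformParams.noiseless()


@pytest.fixture
def well_formed_exam(noiseless_params):
    """A valid six-segment, 101-sample grade-0 exam."""
    return simulate_exam(0, noiseless_params, exam_id="fx-0", patient_id="pt-0")


def make_record(
    exam_id="e1",
    patient_id="p1",
    exam_day=0.0,
    grade_2d=0,
    grade_combined=0,
    rv_lv_ratio=0.7,
    age_years=67.0,
    saps2=35,
    cardiomyopathy=False,
    outcome=Outcome.DISCHARGED_ALIVE,
    outcome_day=10.0,
) -> ExamRecord:
    return ExamRecord(
        exam_id=exam_id,
        patient_id=patient_id,
        exam_day=exam_day,
        grade_2d=grade_2d,
        grade_combined=grade_combined,
        rv_lv_ratio=rv_lv_ratio,
        age_years=age_years,
        saps2=saps2,
        cardiomyopathy=cardiomyopathy,
        outcome=outcome,
        outcome_day=outcome_day,
    )


@pytest.fixture
def record_factory():
    return make_record
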