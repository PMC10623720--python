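"""Exception hierarchy for strain parsing, feature extraction and cohort stats.

All validation failures raise a subclass of :class:`PsmStrainError` so callers
can catch one base type; the leaf classes mirror the distinct failure modes of
each pipeline stage (malformed traces, degenerate agreement tables, ...).
"""


class PsmStrainError(Exception):
    """Base class for all package errors."""


class MissingSegment(PsmStrainError):
    """An exam lacks one of the six required mid-ventricular segments."""


class MalformedTrace(PsmStrainError):
    """A strain trace violates its sampling invariants (monotone time, length)."""


class InvalidMetadata(PsmStrainError):
    """Exam-level metadata is inconsistent (AVC outside cycle, bad heart rate)."""


class ValidationError(PsmStrainError):
    """A cohort record violates its field-level invariants."""


class DuplicateExam(PsmStrainError):
    """Two rows claim the same (patient_id, exam_day) or the same exam_id."""


class DegenerateExam(PsmStrainError):
    """Normalization is undefined: no strictly positive strain sample."""


class WindowOutOfRange(PsmStrainError):
    """A partial-AUC window falls outside the sampled time range."""


class DomainError(PsmStrainError):
    """A numeric argument is outside its mathematical domain."""


class InsufficientGroup(PsmStrainError):
    """A grade group has too few observations for the requested test."""


class DegenerateAgreement(PsmStrainError):
    """Agreement statistic undefined (expected agreement 1 or zero variance)."""


class UndefinedMetric(PsmStrainError):
    """A diagnostic metric has an empty margin (no positives or negatives)."""


class ConfigError(PsmStrainError):
    """A configuration value is invalid (unknown field, bad transition matrix)."""


class MissingValue(PsmStrainError):
    """A required value (grade or RV/LV ratio) is missing for this operation."""


class ChronologyError(PsmStrainError):
    """Exam days are inconsistent with the recorded outcome day."""


class NoEvents(PsmStrainError):
    """A survival fit was requested on data containing no events."""


class CalibrationError(PsmStrainError):
    """A requested simulation target (e.g. kappa) is unattainable."""
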