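"""Grade-stratified comparisons, agreement, diagnostics and reclassification.

Continuous metrics are compared across septal-motion grades with the
Kruskal-Wallis rank-sum test; families of p-values are adjusted with
Benjamini-Hochberg, and significant omnibus tests trigger pairwise rank-sum
post-hocs (their own BH family of three). Inter-rater agreement uses Fleiss'
kappa with a percentile bootstrap CI (resampling exams) for categorical grades
and ICC(2,1) (two-way random effects, absolute agreement, single measure) for
continuous measurements. Diagnostic sensitivity/specificity carry exact
Clopper-Pearson 95% CIs.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    ConfigError,
    DegenerateAgreement,
    DomainError,
    InsufficientGroup,
    UndefinedMetric,
)
from .types import ExamRecord, RaterGrades

GRADES = (0, 1, 2)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DomainError("bh_adjust: empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DomainError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class GradeComparisonResult:
    """Kruskal-Wallis comparison of one metric across grades."""

    metric: str
    n_per_grade: dict[int, int]
    median_per_grade: dict[int, float]
    iqr_per_grade: dict[int, tuple[float, float]]
    statistic: float
    p_raw: float
    p_adjusted: Optional[float] = None
    posthoc: Optional[dict[tuple[int, int], float]] = None  # BH-adjusted pair p's


def kruskal_by_grade(
    values: Sequence[float],
    grades: Sequence[int],
    metric: str = "",
    posthoc_alpha: float = 0.05,
) -> GradeComparisonResult:
    """Kruskal-Wallis across grade groups with rank-sum post-hocs.

    Pairwise Wilcoxon rank-sum tests (BH-adjusted over the three pairs) are run
    only when the omnibus p-value is <= ``posthoc_alpha``. Missing values are
    dropped pairwise.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(grades, dtype=float)
    keep = np.isfinite(v) & np.isfinite(g)
    v, g = v[keep], g[keep].astype(int)
    levels = sorted(set(g.tolist()))
    if len(levels) < 2:
        raise InsufficientGroup(f"{metric}: need >= 2 grade groups, got {len(levels)}")
    groups = [v[g == lev] for lev in levels]
    for lev, grp in zip(levels, groups):
        if len(grp) < 2:
            raise InsufficientGroup(f"{metric}: grade {lev} has {len(grp)} < 2 observations")
    stat, p = stats.kruskal(*groups)
    posthoc = None
    if p <= posthoc_alpha and len(levels) >= 3:
        pairs = list(itertools.combinations(levels, 2))
        raw = [stats.ranksums(v[g == a], v[g == b]).pvalue for a, b in pairs]
        adj = bh_adjust(raw)
        posthoc = {pair: float(pa) for pair, pa in zip(pairs, adj)}
    q = {
        lev: (
            float(np.percentile(grp, 25)),
            float(np.percentile(grp, 75)),
        )
        for lev, grp in zip(levels, groups)
    }
    return GradeComparisonResult(
        metric=metric,
        n_per_grade={lev: int(len(grp)) for lev, grp in zip(levels, groups)},
        median_per_grade={lev: float(np.median(grp)) for lev, grp in zip(levels, groups)},
        iqr_per_grade=q,
        statistic=float(stat),
        p_raw=float(p),
        posthoc=posthoc,
    )


def compare_metrics_by_grade(
    df: pd.DataFrame, metrics: Sequence[str], grade_col: str = "grade_combined"
) -> list[GradeComparisonResult]:
    """One Kruskal-Wallis per metric; BH adjustment over the metric family."""
    results = [
        kruskal_by_grade(df[m].to_numpy(), df[grade_col].to_numpy(), metric=m)
        for m in metrics
    ]
    adj = bh_adjust([r.p_raw for r in results])
    return [
        GradeComparisonResult(
            metric=r.metric,
            n_per_grade=r.n_per_grade,
            median_per_grade=r.median_per_grade,
            iqr_per_grade=r.iqr_per_grade,
            statistic=r.statistic,
            p_raw=r.p_raw,
            p_adjusted=float(a),
            posthoc=r.posthoc,
        )
        for r, a in zip(results, adj)
    ]


def _ratings_table(ratings: Sequence[RaterGrades]) -> np.ndarray:
    n_raters = {len(r.grades) for r in ratings}
    if len(n_raters) != 1:
        raise DegenerateAgreement("all exams must be rated by the same rater count")
    if n_raters.pop() < 2 or len(ratings) < 2:
        raise DegenerateAgreement("need >= 2 raters and >= 2 exams")
    raw = np.array([r.grades for r in ratings], dtype=int)
    counts, _ = aggregate_raters(raw, n_cat=3)
    return counts


def _fleiss_point(counts: np.ndarray) -> float:
    used = counts.sum(axis=0) > 0
    if used.sum() <= 1:
        raise DegenerateAgreement(
            "all ratings in a single category: expected agreement is 1, kappa undefined"
        )
    return float(fleiss_kappa(counts, method="fleiss"))


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    n_exams: int
    n_raters: int
    n_boot: int
    seed: int


def fleiss_kappa_ci(
    ratings: Sequence[RaterGrades], n_boot: int = 2000, seed: int = 0
) -> KappaResult:
    """Fleiss' kappa with a seeded percentile bootstrap CI over exams."""
    counts = _ratings_table(ratings)
    point = _fleiss_point(counts)
    rng = np.random.default_rng(seed)
    n = counts.shape[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = counts[idx]
        try:
            boots[b] = _fleiss_point(sample)
        except DegenerateAgreement:
            boots[b] = 1.0  # resample collapsed to one category: perfect agreement
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return KappaResult(
        kappa=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_exams=n,
        n_raters=int(np.asarray([len(r.grades) for r in ratings]).max()),
        n_boot=n_boot,
        seed=seed,
    )


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n_exams: int
    n_raters: int
    p: float


def icc_agreement(measurements: np.ndarray) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``measurements`` is (n_exams, n_raters). The F-based 95% CI follows the
    standard two-way random-effects construction.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise DegenerateAgreement("need a (>=3 exams, >=2 raters) matrix")
    if np.ptp(m) == 0:
        raise DegenerateAgreement("zero total variance: ICC undefined")
    import pingouin as pg

    n, k = m.shape
    long = pd.DataFrame(
        {
            "exam": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "value": m.ravel(),
        }
    )
    icc_table = pg.intraclass_corr(
        data=long, targets="exam", raters="rater", ratings="value"
    ).set_index("Type")
    # ICC(A,1): two-way, absolute agreement, single rater == ICC(2,1)
    row = icc_table.loc["ICC(A,1)"]
    ci_col = "CI95%" if "CI95%" in icc_table.columns else "CI95"
    lo, hi = row[ci_col]
    return IccResult(
        icc=float(row["ICC"]),
        ci_low=float(lo),
        ci_high=float(hi),
        n_exams=n,
        n_raters=k,
        p=float(row["pval"]),
    )


@dataclass(frozen=True)
class DiagnosticResult:
    sensitivity: float
    sens_ci: tuple[float, float]
    specificity: float
    spec_ci: tuple[float, float]
    tp: int
    fp: int
    fn: int
    tn: int


def diag_metrics(
    test_positive: Sequence[bool], condition_positive: Sequence[bool]
) -> DiagnosticResult:
    """Sensitivity and specificity with exact Clopper-Pearson 95% CIs."""
    t = np.asarray(test_positive, dtype=bool)
    c = np.asarray(condition_positive, dtype=bool)
    if t.shape != c.shape:
        raise DomainError("test and condition vectors must have equal length")
    tp = int(np.sum(t & c))
    fp = int(np.sum(t & ~c))
    fn = int(np.sum(~t & c))
    tn = int(np.sum(~t & ~c))
    if tp + fn == 0:
        raise UndefinedMetric("no condition-positive exams: sensitivity undefined")
    if tn + fp == 0:
        raise UndefinedMetric("no condition-negative exams: specificity undefined")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_ci = proportion_confint(tp, tp + fn, alpha=0.05, method="beta")
    spec_ci = proportion_confint(tn, tn + fp, alpha=0.05, method="beta")
    return DiagnosticResult(
        sensitivity=float(sens),
        sens_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity=float(spec),
        spec_ci=(float(spec_ci[0]), float(spec_ci[1])),
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def cohort_summary(
    records: Sequence[ExamRecord], by: str, percent_decimals: int = 0
) -> pd.DataFrame:
    """Counts, percentages and where sensible median/IQR per group of ``by``.

    Percentages use the number of non-missing values of ``by`` as denominator
    and are rounded to ``percent_decimals`` (default: nearest integer, the
    usual reporting precision).
    """
    from .strain_io import cohort_frame

    if not records:
        raise ConfigError("empty cohort")
    df = cohort_frame(records)
    if by not in df.columns:
        raise ConfigError(f"unknown grouping field {by!r}")
    col = df[by].dropna()
    denom = len(col)
    counts = col.value_counts().sort_index()
    out = pd.DataFrame(
        {
            "group": counts.index,
            "count": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / denom, percent_decimals),
        }
    )
    if percent_decimals == 0:
        out["percent"] = out["percent"].astype(int)
    return out.reset_index(drop=True)


def group_median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and 25th/75th percentiles with NaN dropped."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return (
        float(np.median(v)),
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


def reclassification_matrix(records: Sequence[ExamRecord]) -> tuple[pd.DataFrame, int]:
    """3x3 table of counts moving from the 2D grade to the combined grade.

    Returns ``(matrix, n_excluded)`` where rows index the 2D-only grade,
    columns the combined (2D + strain) grade, and ``n_excluded`` counts records
    missing either grade.
    """
    mat = np.zeros((3, 3), dtype=int)
    excluded = 0
    for r in records:
        if r.grade_2d is None or r.grade_combined is None:
            excluded += 1
            continue
        mat[r.grade_2d, r.grade_combined] += 1
    df = pd.DataFrame(
        mat,
        index=pd.Index(GRADES, name="grade_2d"),
        columns=pd.Index(GRADES, name="grade_combined"),
    )
    return df, excluded
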