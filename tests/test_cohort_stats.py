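"""BH adjustment, Kruskal-Wallis, agreement statistics and diagnostics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from psmstrain.cohort_stats import (
    bh_adjust,
    cohort_summary,
    diag_metrics,
    fleiss_kappa_ci,
    icc_agreement,
    kruskal_by_grade,
    reclassification_matrix,
)
from psmstrain.errors import (
    DegenerateAgreement,
    DomainError,
    InsufficientGroup,
    UndefinedMetric,
)
from psmstrain.types import RaterGrades


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    """Hand-applied step-up formula: p_(i) * m / i with monotone enforcement."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@pytest.mark.parametrize(
    "pvals",
    [
        [0.03],
        [0.01, 0.02, 0.03, 0.04],
        [0.5, 0.001, 0.04, 0.9, 0.2],
    ],
)
def test_bh_matches_stepup_formula(pvals):
    np.testing.assert_allclose(bh_adjust(pvals), _bh_oracle(pvals))


def test_bh_known_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
def test_bh_dominance_and_permutation_invariance(pvals):
    adj = bh_adjust(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    # adjusting already-adjusted p never decreases them
    assert np.all(bh_adjust(adj) >= adj - 1e-12)
    perm = np.random.default_rng(0).permutation(len(pvals))
    np.testing.assert_allclose(bh_adjust(np.asarray(pvals)[perm]), adj[perm])


def test_bh_rejects_out_of_range():
    with pytest.raises(DomainError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# Kruskal-Wallis by grade
# ---------------------------------------------------------------------------

def test_kw_fully_separated_groups():
    values = list(range(1, 21)) + list(range(101, 121)) + list(range(201, 221))
    grades = [0] * 20 + [1] * 20 + [2] * 20
    res = kruskal_by_grade(values, grades, metric="sep")
    assert res.p_raw < 0.001
    assert res.posthoc is not None and len(res.posthoc) == 3
    assert all(p < 0.05 for p in res.posthoc.values())
    assert res.median_per_grade[1] == 110.5


def test_kw_two_groups_equals_ranksum():
    """With two tie-free groups, KW is the chi-square(1) form of the rank-sum z."""
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 25), rng.normal(0.7, 1, 30)
    res = kruskal_by_grade(
        np.concatenate([a, b]), [0] * 25 + [1] * 30, metric="two"
    )
    z = stats.ranksums(a, b).statistic
    p_oracle = stats.chi2.sf(z**2, df=1)
    assert abs(res.p_raw - p_oracle) < 1e-6


def test_kw_insufficient_group():
    with pytest.raises(InsufficientGroup):
        kruskal_by_grade([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 2])


# ---------------------------------------------------------------------------
# Fleiss kappa
# ---------------------------------------------------------------------------

def test_fleiss_perfect_agreement():
    ratings = [
        RaterGrades(f"e{i}", (g, g))
        for i, g in enumerate([0, 0, 1, 2, 1, 0, 2, 2, 1, 0])
    ]
    res = fleiss_kappa_ci(ratings, n_boot=50, seed=1)
    assert res.kappa == pytest.approx(1.0)


def test_fleiss_matches_hand_formula_on_4x3_table():
    """(0,0),(1,1),(2,1),(0,2): P_o=1/2, P_e=11/32, kappa=5/21."""
    ratings = [
        RaterGrades("a", (0, 0)),
        RaterGrades("b", (1, 1)),
        RaterGrades("c", (2, 1)),
        RaterGrades("d", (0, 2)),
    ]
    res = fleiss_kappa_ci(ratings, n_boot=10, seed=0)
    assert abs(res.kappa - 5.0 / 21.0) < 1e-9


def test_fleiss_degenerate_single_category():
    ratings = [RaterGrades(f"e{i}", (1, 1)) for i in range(5)]
    with pytest.raises(DegenerateAgreement):
        fleiss_kappa_ci(ratings, n_boot=10, seed=0)


def test_fleiss_bootstrap_reproducible_and_ci_shrinks():
    rng = np.random.default_rng(9)
    big = [
        RaterGrades(f"e{i}", (int(g), int(g) if rng.random() < 0.8 else int(rng.choice(3))))
        for i, g in enumerate(rng.choice(3, size=500))
    ]
    r1 = fleiss_kappa_ci(big, n_boot=200, seed=7)
    r2 = fleiss_kappa_ci(big, n_boot=200, seed=7)
    assert (r1.kappa, r1.ci_low, r1.ci_high) == (r2.kappa, r2.ci_low, r2.ci_high)
    small = fleiss_kappa_ci(big[:50], n_boot=200, seed=7)
    assert (r1.ci_high - r1.ci_low) < (small.ci_high - small.ci_low)


def test_fleiss_null_random_grades_ci_covers_zero():
    rng = np.random.default_rng(11)
    ratings = [
        RaterGrades(f"e{i}", (int(rng.choice(3)), int(rng.choice(3))))
        for i in range(310)
    ]
    res = fleiss_kappa_ci(ratings, n_boot=500, seed=4)
    assert res.ci_low <= 0.0 <= res.ci_high


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_icc_identical_measurements():
    m = np.tile(np.arange(10, dtype=float)[:, None], (1, 2))
    res = icc_agreement(m)
    assert res.icc == pytest.approx(1.0)


def test_icc_zero_variance_degenerate():
    with pytest.raises(DegenerateAgreement):
        icc_agreement(np.ones((10, 2)))


def test_icc_variance_component_recovery():
    """Subject variance 4, error variance 1 -> true ICC 0.8."""
    rng = np.random.default_rng(5)
    m = rng.normal(0, 2, size=(200, 1)) + rng.normal(0, 1, size=(200, 2))
    res = icc_agreement(m)
    assert 0.72 <= res.icc <= 0.88


def test_icc_null_no_subject_effect():
    m = np.random.default_rng(7).normal(0, 1, size=(200, 2))
    res = icc_agreement(m)
    assert -0.2 <= res.icc <= 0.2


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def test_diag_perfect_test():
    cond = np.array([True] * 5 + [False] * 5)
    res = diag_metrics(cond, cond)
    assert res.sensitivity == 1.0 and res.specificity == 1.0


def test_diag_toy_table():
    test = np.array([True] * 26 + [False] * 24 + [False] * 100)
    cond = np.array([True] * 50 + [False] * 100)
    res = diag_metrics(test, cond)
    assert res.sensitivity == pytest.approx(0.52)
    assert res.specificity == pytest.approx(1.0)
    assert (res.tp, res.fn, res.fp, res.tn) == (26, 24, 0, 100)
    assert res.sens_ci[0] <= 0.52 <= res.sens_ci[1]


def test_diag_exact_ci_at_full_success():
    """x = n = 100: exact lower bound is (alpha/2)^(1/n)."""
    test = np.array([True] * 100 + [False] * 10)
    cond = np.array([True] * 100 + [False] * 10)
    res = diag_metrics(test, cond)
    closed_form = 0.025 ** (1.0 / 100.0)
    assert abs(res.sens_ci[0] - closed_form) < 1e-9

    # cross-check via binomial-CDF root finding
    from scipy.optimize import brentq

    root = brentq(lambda p: stats.binom.sf(99, 100, p) - 0.025, 1e-9, 1 - 1e-12)
    assert abs(res.sens_ci[0] - root) < 1e-7


def test_diag_empty_margin():
    with pytest.raises(UndefinedMetric):
        diag_metrics([True, False], [True, True])


# ---------------------------------------------------------------------------
# Summary and reclassification
# ---------------------------------------------------------------------------

def test_single_group_is_100_percent(record_factory):
    records = [
        record_factory(exam_id=f"e{i}", patient_id=f"p{i}", grade_combined=1)
        for i in range(7)
    ]
    out = cohort_summary(records, by="grade_combined")
    assert out["percent"].tolist() == [100]


def test_reclassification_conservation_and_diagonal(record_factory):
    rng = np.random.default_rng(2)
    records = [
        record_factory(
            exam_id=f"e{i}",
            patient_id=f"p{i}",
            grade_2d=int(rng.choice(3)),
            grade_combined=int(rng.choice(3)),
        )
        for i in range(100)
    ]
    mat, excluded = reclassification_matrix(records)
    assert mat.to_numpy().sum() == 100 and excluded == 0
    concordant = [
        record_factory(exam_id=f"c{i}", patient_id=f"q{i}", grade_2d=g, grade_combined=g)
        for i, g in enumerate([0, 1, 2, 1])
    ]
    mat2, _ = reclassification_matrix(concordant)
    off_diag = mat2.to_numpy() - np.diag(np.diag(mat2.to_numpy()))
    assert off_diag.sum() == 0


def test_reclassification_row_sums_match_summary(record_factory):
    rng = np.random.default_rng(4)
    records = [
        record_factory(
            exam_id=f"e{i}",
            patient_id=f"p{i}",
            grade_2d=int(rng.choice(3)),
            grade_combined=int(rng.choice(3)),
        )
        for i in range(60)
    ]
    mat, _ = reclassification_matrix(records)
    summary = cohort_summary(records, by="grade_2d")
    counts = dict(zip(summary["group"].astype(int), summary["count"]))
    for g in (0, 1, 2):
        assert mat.loc[g].sum() == counts.get(g, 0)
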