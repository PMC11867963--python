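import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oncoscreen.differential_screen import (
    FLAG_COLUMNS,
    TestResult,
    bh_adjust,
    one_way_anova,
    run_screen,
    student_t_test,
    successive_upregulation,
    venn_counts,
)
from oncoscreen.errors import DataError
from oncoscreen.signature_scoring import signature_score, tertile_groups, zscore_matrix
from oncoscreen.survival_analysis import best_cutoff_table
from oncoscreen.types import CohortAnnotation, ExpressionMatrix


def _hand_pooled_t(a, b):
    """Independent oracle: textbook pooled-variance t with n1+n2-2 df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def test_t_test_matches_hand_formula():
    a, b = [1, 2, 3, 4], [2, 3, 4, 5]
    res = student_t_test(a, b)
    t, p = _hand_pooled_t(a, b)
    assert res.statistic == pytest.approx(t, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)
    assert res.direction == 1


def test_t_test_identical_groups():
    res = student_t_test([1, 2, 3], [1, 2, 3])
    assert res.statistic == 0 and res.p_value == 1


def test_t_test_swap_flips_sign_keeps_p(rng):
    a, b = rng.normal(size=8), rng.normal(size=6)
    fwd, rev = student_t_test(a, b), student_t_test(b, a)
    assert fwd.statistic == pytest.approx(-rev.statistic)
    assert fwd.p_value == pytest.approx(rev.p_value)


def test_t_test_degenerate_zero_variance_unequal_means():
    res = student_t_test([1, 1], [2, 2])
    assert res.p_value == 0 and res.degenerate


def test_t_test_group_size_error():
    with pytest.raises(DataError):
        student_t_test([1], [1, 2])


def _hand_anova_f(groups):
    """Independent oracle: between/within sum-of-squares F."""
    groups = [np.asarray(g, float) for g in groups]
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k, n = len(groups), all_v.size
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = stats.f.sf(f, k - 1, n - k)
    return f, p


def test_anova_matches_hand_formula(rng):
    groups = [rng.normal(size=5), rng.normal(loc=0.3, size=7), rng.normal(size=6)]
    res = one_way_anova(groups)
    f, p = _hand_anova_f(groups)
    assert res.statistic == pytest.approx(f, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def test_anova_identical_groups_f_zero():
    res = one_way_anova([[1, 1], [1, 1], [1, 1]])
    assert res.statistic == 0 and res.p_value == 1


def test_anova_two_groups_equals_t_squared(rng):
    a, b = rng.normal(size=6), rng.normal(size=9)
    f = one_way_anova([a, b]).statistic
    t = student_t_test(a, b).statistic
    assert f == pytest.approx(t**2, rel=1e-10)


def _hand_bh(p):
    """Step-up: q_(i) = min_{j>=i}(p_(j) * m / j), capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1)
    return q


def test_bh_hand_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_single_p_unchanged():
    assert bh_adjust([0.03])[0] == pytest.approx(0.03)


def test_bh_matches_step_up_formula(rng):
    p = rng.uniform(size=40)
    np.testing.assert_allclose(bh_adjust(p), _hand_bh(p), atol=1e-12)


def test_bh_nondecreasing_in_sorted_order(rng):
    p = rng.uniform(size=25)
    q = bh_adjust(p)
    assert np.all(np.diff(q[np.argsort(p)]) >= -1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(DataError):
        bh_adjust([0.5, 1.2])


@pytest.mark.parametrize(
    "means,q,expected",
    [((1, 2, 3), 0.001, True), ((1, 3, 2), 0.001, False), ((1, 2, 3), 0.2, False)],
)
def test_successive_upregulation(means, q, expected):
    anova = TestResult("g", 5.0, 0.001, means, 1, q_value=q)
    assert successive_upregulation(means, anova) is expected


# ---------------------------------------------------------------- run_screen

def _toy_inputs():
    """4 genes x 16 samples with known flag outcomes."""
    rng = np.random.default_rng(5)
    normals = [f"N{i}" for i in range(4)]
    tumors = [f"T{i}" for i in range(12)]
    latent = np.linspace(0, 1, 12)
    rows = {
        # strong everything: up in tumor, monotone with latent, up in advanced
        "ALL": np.r_[rng.normal(0, 0.1, 4), 3 + 2 * latent + rng.normal(0, 0.1, 12)],
        # tumor-shifted only
        "TUMOR_ONLY": np.r_[rng.normal(0, 0.1, 4), 3 + rng.normal(0, 0.1, 12)],
        # nothing
        "FLAT": rng.normal(0, 0.1, 16),
        # down in tumor
        "DOWN": np.r_[rng.normal(3, 0.1, 4), rng.normal(0, 0.1, 12)],
    }
    expr = ExpressionMatrix(
        data=pd.DataFrame(rows, index=normals + tumors).T
    )
    ann = pd.DataFrame(index=normals + tumors)
    ann["tissue"] = ["normal"] * 4 + ["tumor"] * 12
    ann["stage"] = ["unknown"] * 4 + ["early"] * 6 + ["advanced"] * 6
    ann["grade"] = "unknown"
    ann["invasiveness"] = "unknown"
    ann["progression"] = np.nan
    ann["survival_time"] = np.nan
    ann["survival_event"] = np.nan
    ann["endpoint"] = "overall"
    annotation = CohortAnnotation(table=ann)
    groups = pd.Series(
        {t: g for t, g in zip(tumors, ["low"] * 4 + ["intermediate"] * 4 + ["high"] * 4)}
    )
    flags = {"ALL": "poor_survival", "TUMOR_ONLY": "none", "FLAT": "none", "DOWN": "none"}
    return expr, annotation, groups, flags


def test_run_screen_toy_flags_and_intersection():
    expr, ann, groups, flags = _toy_inputs()
    out = run_screen(expr, ann, groups, flags)
    assert out.loc["ALL", list(FLAG_COLUMNS)].all()
    assert bool(out.loc["ALL", "oncogenic_target"])
    assert not out.loc["TUMOR_ONLY", "successive_up"]
    assert not out.loc["DOWN", "up_in_tumor"]
    assert list(out.index[out["oncogenic_target"]]) == ["ALL"]


def test_run_screen_invariant_to_gene_order():
    expr, ann, groups, flags = _toy_inputs()
    out = run_screen(expr, ann, groups, flags)
    shuffled = ExpressionMatrix(data=expr.data.iloc[::-1])
    out2 = run_screen(shuffled, ann, groups, flags)
    pd.testing.assert_frame_equal(out.sort_index(), out2.sort_index())


def test_run_screen_empty_stratum_named():
    expr, ann, groups, flags = _toy_inputs()
    table = ann.table.copy()
    table.loc[table["stage"] == "advanced", "stage"] = "early"
    with pytest.raises(DataError, match="advanced"):
        run_screen(expr, CohortAnnotation(table=table), groups, flags)


def test_venn_counts_partition_and_all_true_cell():
    expr, ann, groups, flags = _toy_inputs()
    out = run_screen(expr, ann, groups, flags)
    venn = venn_counts(out)
    assert venn["count"].sum() == len(out)
    all_true = venn.loc[venn[list(FLAG_COLUMNS)].all(axis=1), "count"].iloc[0]
    assert all_true == 1


def test_null_cohort_intersection_is_empty(null_cohort):
    """With no planted effects the four-criteria intersection is ~0."""
    ann = null_cohort.annotation
    z = zscore_matrix(null_cohort.expression, ann.tumors)
    groups = tertile_groups(signature_score(z, null_cohort.emt_set))
    surv = best_cutoff_table(null_cohort.expression, ann)
    out = run_screen(null_cohort.expression, ann, groups, surv["flag"])
    assert out["oncogenic_target"].sum() <= 1
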