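import numpy as np
import pandas as pd
import pytest

from oncoscreen.association_screen import (
    common_regulators,
    pearson,
    rank_negative_regulators,
    signature_correlation,
    summarize_dependency,
    tf_consistency_report,
)
from oncoscreen.errors import DataError
from oncoscreen.signature_scoring import SignatureScore
from oncoscreen.types import ExpressionMatrix, GeneSet, interaction_table


# ---------------------------------------------------------------- pearson

def test_pearson_perfect_anticorrelation():
    x = np.arange(10.0)
    res = pearson(x, -x)
    assert res.r == pytest.approx(-1.0)


def test_pearson_matches_hand_formula(rng):
    x, y = rng.normal(size=20), rng.normal(size=20)
    res = pearson(x, y)
    xc, yc = x - x.mean(), y - y.mean()
    r_hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
    assert res.r == pytest.approx(r_hand, abs=1e-12)
    from scipy import stats

    t = r_hand * np.sqrt(18 / (1 - r_hand**2))
    assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 18), rel=1e-10)


def test_pearson_pairwise_drops_missing():
    x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
    y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    assert pearson(x, y).n == 4


def test_pearson_constant_vector_error():
    with pytest.raises(DataError):
        pearson([1, 1, 1, 1], [1, 2, 3, 4])


# ---------------------------------------------------------------- miRNA ranking

def test_planted_mirnas_rank_first(planted_cohort):
    tumors = planted_cohort.annotation.tumors
    signature = GeneSet("PLANTED", "", planted_cohort.truth.planted_gene_ids)
    ranking = rank_negative_regulators(
        planted_cohort.mirna_expression.subset_samples(tumors),
        planted_cohort.expression.subset_samples(tumors),
        signature,
        top_k=2,
    )
    assert set(ranking.top) == set(planted_cohort.truth.planted_mirna_ids)
    assert len(ranking.top) == 2
    assert (ranking.table.loc[list(ranking.top), "mean_r"] < 0).all()


def test_mirna_matching_signature_profile_ranks_last(planted_cohort):
    tumors = planted_cohort.annotation.tumors
    signature = GeneSet("PLANTED", "", planted_cohort.truth.planted_gene_ids)
    gene_expr = planted_cohort.expression.subset_samples(tumors)
    profile = gene_expr.data.loc[list(signature.members)].mean(axis=0)
    mir = planted_cohort.mirna_expression.subset_samples(tumors).data.copy()
    mir.loc["hsa-mir-mimic"] = profile.to_numpy()
    ranking = rank_negative_regulators(
        ExpressionMatrix(data=mir), gene_expr, signature
    )
    assert ranking.table.index[-1] == "hsa-mir-mimic"


def test_background_mirna_mean_r_near_zero(planted_cohort):
    tumors = planted_cohort.annotation.tumors
    signature = GeneSet("PLANTED", "", planted_cohort.truth.planted_gene_ids)
    ranking = rank_negative_regulators(
        planted_cohort.mirna_expression.subset_samples(tumors),
        planted_cohort.expression.subset_samples(tumors),
        signature,
    )
    background = ranking.table.drop(index=list(planted_cohort.truth.planted_mirna_ids))
    assert background["mean_r"].abs().mean() < 0.1


def test_ranking_invariant_to_sample_order_and_gene_rescaling(planted_cohort):
    tumors = planted_cohort.annotation.tumors
    signature = GeneSet("PLANTED", "", planted_cohort.truth.planted_gene_ids)
    mir = planted_cohort.mirna_expression.subset_samples(tumors)
    genes = planted_cohort.expression.subset_samples(tumors)
    base = rank_negative_regulators(mir, genes, signature)
    shuffled = ExpressionMatrix(data=mir.data.iloc[:, ::-1])
    scaled = genes.data.copy()
    scaled.iloc[0] = scaled.iloc[0] * 7.5 + 3.0
    alt = rank_negative_regulators(shuffled, ExpressionMatrix(data=scaled), signature)
    assert list(base.table.index) == list(alt.table.index)
    np.testing.assert_allclose(base.table["mean_r"], alt.table["mean_r"], atol=1e-10)


def test_ranking_requires_shared_samples(planted_cohort):
    signature = GeneSet("PLANTED", "", planted_cohort.truth.planted_gene_ids)
    mir = planted_cohort.mirna_expression
    renamed = ExpressionMatrix(
        data=mir.data.rename(columns={c: f"other-{c}" for c in mir.data.columns})
    )
    with pytest.raises(DataError):
        rank_negative_regulators(renamed, planted_cohort.expression, signature)


# ---------------------------------------------------------------- signature corr

def _scores(values, prefix="s"):
    return [SignatureScore(f"{prefix}{i}", v, 1.0) for i, v in enumerate(values)]


def test_signature_correlation_affine_invariance(rng):
    vals = rng.normal(size=12)
    res = signature_correlation(_scores(vals), _scores(2 * vals))
    assert res.r == pytest.approx(1.0)


def test_signature_correlation_disjoint_samples_error(rng):
    with pytest.raises(DataError):
        signature_correlation(_scores(rng.normal(size=5), "a"), _scores(rng.normal(size=5), "b"))


def test_hub_score_anticorrelates_with_suppressor_mirnas(planted_cohort):
    from oncoscreen.signature_scoring import signature_score, zscore_matrix

    tumors = planted_cohort.annotation.tumors
    z_gene = zscore_matrix(planted_cohort.expression, tumors)
    z_mir = zscore_matrix(planted_cohort.mirna_expression, tumors)
    hub = signature_score(z_gene, GeneSet("PLANTED", "", planted_cohort.truth.planted_gene_ids))
    mir = signature_score(z_mir, GeneSet("MIR", "", planted_cohort.truth.planted_mirna_ids))
    res = signature_correlation(hub, mir)
    assert res.r < 0 and res.p_value < 0.05


# ---------------------------------------------------------------- dependency

def test_dependency_zero_scores_mean_zero():
    table = pd.DataFrame(0.0, index=["A", "B"], columns=["line1", "line2"])
    summary = summarize_dependency(table, GeneSet("S", "", ("A", "B")))
    assert (summary == 0).all()
    assert summary.attrs["overall_mean"] == 0


def test_dependency_negative_scores_mean_negative():
    table = pd.DataFrame(-1.0, index=["A", "B"], columns=["line1"])
    summary = summarize_dependency(table, GeneSet("S", "", ("A", "B")))
    assert summary.iloc[0] == pytest.approx(-1.0)


def test_dependency_missing_gene_uses_present_only():
    table = pd.DataFrame({"line1": [1.0, 3.0]}, index=["A", "B"])
    summary = summarize_dependency(table, GeneSet("S", "", ("A", "B", "C")))
    assert summary.iloc[0] == pytest.approx(2.0)
    assert summary.attrs["missing_genes"] == ("C",)


def test_dependency_linear_in_table(rng):
    table = pd.DataFrame(rng.normal(size=(4, 3)), index=list("ABCD"), columns=list("xyz"))
    sig = GeneSet("S", "", ("A", "C"))
    doubled = summarize_dependency(2 * table, sig)
    np.testing.assert_allclose(doubled, 2 * summarize_dependency(table, sig))


def test_dependency_zero_overlap_error():
    table = pd.DataFrame({"line1": [1.0]}, index=["A"])
    with pytest.raises(DataError):
        summarize_dependency(table, GeneSet("S", "", ("Z",)))


# ---------------------------------------------------------------- TF report

def test_tf_full_coverage():
    sig = GeneSet("S", "", tuple(f"G{i}" for i in range(8)))
    rows = [("NFKB1", f"G{i}", 1.0) for i in range(8)] + [("OTHER", "G0", 1.0)]
    preds = interaction_table(rows, "htftarget")
    report = tf_consistency_report(preds, sig)
    assert report.loc["NFKB1", "gene_coverage"] == pytest.approx(1.0)
    assert report.loc["OTHER", "gene_coverage"] == pytest.approx(1 / 8)


def test_tf_empty_predictions_zero_coverage():
    report = tf_consistency_report(
        interaction_table([], "htftarget"), GeneSet("S", "", ("A",))
    )
    assert report.empty


def test_common_regulators_venn_intersection():
    rows = [
        ("TFA", "hsa-mir-1", 1.0),
        ("TFA", "hsa-mir-2", 1.0),
        ("TFB", "hsa-mir-1", 1.0),
    ]
    preds = interaction_table(rows, "transmir")
    assert common_regulators(preds, ["hsa-mir-1", "hsa-mir-2"]) == {"TFA"}
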