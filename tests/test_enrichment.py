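from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from oncoscreen.enrichment import (
    RankedList,
    enrichment_score,
    gsea,
    ora_test,
    rank_by_signal_to_noise,
)
from oncoscreen.errors import DataError, UndefinedStatisticError
from oncoscreen.signature_scoring import median_split, signature_score, zscore_matrix
from oncoscreen.types import ExpressionMatrix, GeneSet


def _brute_force_es(metric, hit, weight=1.0):
    """Independent oracle: literal walk down the list per the definition."""
    n, nh = len(metric), sum(hit)
    denom = sum(abs(m) ** weight for m, h in zip(metric, hit) if h)
    run, best_pos, best_neg = 0.0, 0.0, 0.0
    for m, h in zip(metric, hit):
        if h:
            run += (abs(m) ** weight) / denom if denom > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        best_pos = max(best_pos, run)
        best_neg = min(best_neg, run)
    # magnitude ties resolve to the positive deviation
    return best_pos if best_pos >= -best_neg - 1e-12 else best_neg


def _ranked(metric, ids=None):
    metric = np.asarray(metric, dtype=float)
    ids = ids or tuple(f"g{i}" for i in range(metric.size))
    return RankedList(feature_ids=tuple(ids), metric_values=metric)


# ---------------------------------------------------------------- s2n

def test_signal_to_noise_matches_hand_computation():
    rng = np.random.default_rng(1)
    values = rng.normal(size=(5, 6))
    genes = [f"g{i}" for i in range(5)]
    samples = [f"s{i}" for i in range(6)]
    expr = ExpressionMatrix(data=pd.DataFrame(values, index=genes, columns=samples))
    phen = pd.Series(["high"] * 3 + ["low"] * 3, index=samples)
    ranked = rank_by_signal_to_noise(expr, phen)
    # hand-computed with the floored-SD convention
    expected = {}
    for i, g in enumerate(genes):
        a, b = values[i, :3], values[i, 3:]
        sa = max(a.std(ddof=1), 0.2 * abs(a.mean()) or 0.2)
        sb = max(b.std(ddof=1), 0.2 * abs(b.mean()) or 0.2)
        expected[g] = (a.mean() - b.mean()) / (sa + sb)
    for g, m in zip(ranked.feature_ids, ranked.metric_values):
        assert m == pytest.approx(expected[g], abs=1e-12)
    assert np.all(np.diff(ranked.metric_values) <= 0)


def test_signal_to_noise_class_swap_negates_and_reverses():
    rng = np.random.default_rng(2)
    values = rng.normal(size=(6, 8))
    expr = ExpressionMatrix(
        data=pd.DataFrame(values, index=[f"g{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(8)])
    )
    phen = pd.Series(["high"] * 4 + ["low"] * 4, index=expr.sample_ids)
    fwd = rank_by_signal_to_noise(expr, phen, positive_class="high")
    rev = rank_by_signal_to_noise(expr, phen, positive_class="low")
    fwd_map = dict(zip(fwd.feature_ids, fwd.metric_values))
    rev_map = dict(zip(rev.feature_ids, rev.metric_values))
    for g in fwd_map:
        assert rev_map[g] == pytest.approx(-fwd_map[g], abs=1e-12)


def test_signal_to_noise_equal_gene_has_zero_metric():
    values = np.vstack([np.r_[np.ones(3), np.ones(3)], np.r_[np.ones(3) * 2, np.zeros(3)]])
    expr = ExpressionMatrix(
        data=pd.DataFrame(values, index=["flat", "diff"], columns=[f"s{i}" for i in range(6)])
    )
    phen = pd.Series(["high"] * 3 + ["low"] * 3, index=expr.sample_ids)
    ranked = rank_by_signal_to_noise(expr, phen)
    assert dict(zip(ranked.feature_ids, ranked.metric_values))["flat"] == 0


# ---------------------------------------------------------------- ES

def test_es_single_member_at_top_is_one():
    ranked = _ranked([3.0, 2.0, 1.0, -1.0])
    es, _, leading = enrichment_score(ranked, GeneSet("S", "", ("g0",)))
    assert es == pytest.approx(1.0)
    assert leading == ("g0",)


METRIC_10 = np.array([2.3, 1.9, 1.2, 0.8, 0.3, -0.1, -0.7, -1.1, -1.8, -2.5])


def test_es_matches_brute_force_on_all_admissible_subsets():
    ranked = _ranked(METRIC_10)
    ids = list(ranked.feature_ids)
    for k in range(1, 10):
        for subset in combinations(range(10), k):
            members = tuple(ids[i] for i in subset)
            hit = [i in set(subset) for i in range(10)]
            es, _, _ = enrichment_score(ranked, GeneSet("S", "", members))
            assert es == pytest.approx(_brute_force_es(METRIC_10, hit), abs=1e-12)


def test_es_weight_zero_is_classical_ks():
    ranked = _ranked(METRIC_10)
    for subset in [(0, 3, 5), (1, 2), (4, 6, 7, 9), (0, 9), (2, 3, 4, 5, 6)]:
        hit = np.array([i in set(subset) for i in range(10)])
        # direct unweighted KS statistic via empirical CDF difference
        d = np.cumsum(np.where(hit, 1 / hit.sum(), -1 / (10 - hit.sum())))
        expected = d[np.argmax(np.abs(d))]
        members = tuple(ranked.feature_ids[i] for i in subset)
        es, _, _ = enrichment_score(ranked, GeneSet("S", "", members), weight=0)
        assert es == pytest.approx(expected, abs=1e-12)


def test_es_reversed_symmetric_list_negates():
    ranked = _ranked(np.array([2.0, 1.0, 0.5, -0.5, -1.0, -2.0]))
    rev = _ranked(ranked.metric_values[::-1] * -1, ids=ranked.feature_ids[::-1])
    members = ("g1", "g2")
    es_fwd, _, _ = enrichment_score(ranked, GeneSet("S", "", members))
    es_rev, _, _ = enrichment_score(rev, GeneSet("S", "", members))
    assert es_rev == pytest.approx(-es_fwd, abs=1e-12)


def test_es_degenerate_sets_rejected():
    ranked = _ranked([1.0, 0.5, -0.5])
    with pytest.raises(UndefinedStatisticError):
        enrichment_score(ranked, GeneSet("S", "", ("g0", "g1", "g2")))
    with pytest.raises(UndefinedStatisticError):
        enrichment_score(ranked, GeneSet("S", "", ("absent",)))


# ---------------------------------------------------------------- gsea

def _cohort_phenotype(cohort):
    z = zscore_matrix(cohort.expression, cohort.annotation.tumors)
    planted = GeneSet("PLANTED", "", cohort.truth.planted_gene_ids)
    return z, median_split(signature_score(z, planted)), planted


def test_gsea_same_seed_reproducible(planted_cohort):
    expr = planted_cohort.expression.subset_samples(planted_cohort.annotation.tumors)
    _, phen, planted = _cohort_phenotype(planted_cohort)
    sets = [planted, planted_cohort.emt_set]
    a = gsea(expr, phen, sets, n_perm=200, seed=9)
    b = gsea(expr, phen, sets, n_perm=200, seed=9)
    assert [(r.es, r.nes, r.nominal_p, r.fdr_q) for r in a] == [
        (r.es, r.nes, r.nominal_p, r.fdr_q) for r in b
    ]


def test_gsea_detects_planted_signature(planted_cohort):
    """The planted module must enrich in the high-score phenotype."""
    expr = planted_cohort.expression.subset_samples(planted_cohort.annotation.tumors)
    _, phen, planted = _cohort_phenotype(planted_cohort)
    (res,) = [r for r in gsea(expr, phen, [planted], n_perm=500, perm_type="phenotype", seed=1)]
    assert res.es > 0 and res.nes > 0
    assert res.fdr_q < 0.05
    assert np.sign(res.nes) == np.sign(res.es)


def test_gsea_filters_sets_outside_size_bounds(planted_cohort):
    expr = planted_cohort.expression.subset_samples(planted_cohort.annotation.tumors)
    _, phen, planted = _cohort_phenotype(planted_cohort)
    tiny = GeneSet("TINY", "", planted.members[:2])
    with pytest.raises(DataError):
        gsea(expr, phen, [tiny], n_perm=100, seed=0)


# ---------------------------------------------------------------- ORA

def _uni(n):
    return GeneSet("U", "", tuple(f"g{i}" for i in range(n)))


def test_ora_closed_form_full_overlap():
    universe = _uni(20)
    subset = GeneSet("S", "", universe.members[:5])
    res = ora_test(subset, subset, universe)
    assert res.p_value == pytest.approx(1 / comb(20, 5), rel=1e-12)
    assert res.overlap == 5


def test_ora_zero_overlap_p_one():
    universe = _uni(20)
    query = GeneSet("Q", "", universe.members[:5])
    other = GeneSet("S", "", universe.members[5:10])
    assert ora_test(query, other, universe).p_value == pytest.approx(1.0)
    assert ora_test(query, other, universe, ease=True).p_value == pytest.approx(1.0)


def test_ora_matches_enumeration_oracle_small_universe():
    """Exact upper-tail probability by combinatorial enumeration, N <= 15."""
    for big_n, big_k, n in [(10, 4, 3), (12, 5, 6), (15, 7, 5)]:
        universe = _uni(big_n)
        anno = GeneSet("S", "", universe.members[:big_k])
        for k in range(0, min(n, big_k) + 1):
            members = universe.members[:k] + universe.members[big_k : big_k + n - k]
            query = GeneSet("Q", "", members)
            exact = sum(
                comb(big_k, j) * comb(big_n - big_k, n - j) for j in range(k, min(n, big_k) + 1)
            ) / comb(big_n, n)
            assert ora_test(query, anno, universe).p_value == pytest.approx(exact, rel=1e-10)


def test_ora_monotone_decreasing_in_overlap():
    universe = _uni(30)
    anno = GeneSet("S", "", universe.members[:10])
    last = 1.1
    for k in range(0, 9):
        members = universe.members[:k] + universe.members[10 : 10 + 8 - k]
        p = ora_test(GeneSet("Q", "", members), anno, universe).p_value
        assert p < last
        last = p


def test_ora_ease_is_more_conservative():
    universe = _uni(25)
    anno = GeneSet("S", "", universe.members[:8])
    query = GeneSet("Q", "", universe.members[:6])
    plain = ora_test(query, anno, universe)
    ease = ora_test(query, anno, universe, ease=True)
    assert ease.p_value > plain.p_value
    assert ease.fold_enrichment == plain.fold_enrichment
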