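"""The four-criteria oncogenic-target screen.

A gene is called an oncogenic target when it is simultaneously

1. upregulated in tumors vs normal tissue (pooled-variance Student's t,
   BH FDR q < q_cut, positive direction),
2. successively upregulated across low -> intermediate -> high
   aggressiveness tertiles (one-way ANOVA q < q_cut AND strictly
   increasing group means),
3. upregulated in advanced- vs early-stage tumors (t-test, q < q_cut,
   positive direction), and
4. associated with poor survival at the best-cutoff split (nominal
   log-rank p < surv_p_cut, high-expression group dying more than
   expected).

BH adjustment is applied within each expression comparison separately
(three independent FDR families); the survival criterion uses nominal p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .types import CohortAnnotation, ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "student_t_test",
    "one_way_anova",
    "bh_adjust",
    "successive_upregulation",
    "run_screen",
    "venn_counts",
    "FLAG_COLUMNS",
]

FLAG_COLUMNS = ("up_in_tumor", "successive_up", "up_in_advanced", "poor_survival")


@dataclass(frozen=True)
class TestResult:
    feature_id: str
    statistic: float
    p_value: float
    group_means: tuple[float, ...]
    direction: int  # sign of (second group mean - first)
    q_value: float = float("nan")
    degenerate: bool = False


TestResult.__test__ = False  # keep pytest from collecting the dataclass


def _as_clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def student_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    feature_id: str = "",
    welch: bool = False,
) -> TestResult:
    """Two-sided pooled-variance Student's t-test (Welch behind a flag).

    The statistic is oriented so that its sign equals
    sign(mean_b - mean_a); a zero pooled variance yields t=0, p=1 for equal
    means and p=0 flagged degenerate for unequal means.
    """
    a, b = _as_clean(group_a), _as_clean(group_b)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 non-missing values")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    direction = int(np.sign(mean_b - mean_a))
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if mean_a == mean_b:
            return TestResult(feature_id, 0.0, 1.0, (mean_a, mean_b), 0)
        return TestResult(
            feature_id, float("inf") * direction, 0.0, (mean_a, mean_b), direction, degenerate=True
        )
    res = stats.ttest_ind(b, a, equal_var=not welch)
    return TestResult(
        feature_id, float(res.statistic), float(res.pvalue), (mean_a, mean_b), direction
    )


def one_way_anova(groups: Sequence[Sequence[float]], feature_id: str = "") -> TestResult:
    """One-way ANOVA across k groups; F with (k-1, N-k) degrees of freedom."""
    cleaned = [_as_clean(g) for g in groups]
    if any(g.size < 2 for g in cleaned):
        raise DataError("each ANOVA group needs at least 2 values")
    means = tuple(float(g.mean()) for g in cleaned)
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return TestResult(feature_id, 0.0, 1.0, means, 0)
    res = stats.f_oneway(*cleaned)
    direction = int(np.sign(means[-1] - means[0]))
    stat, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(stat):  # zero within-group variance, unequal means
        return TestResult(feature_id, float("inf"), 0.0, means, direction, degenerate=True)
    return TestResult(feature_id, stat, p, means, direction)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def successive_upregulation(
    means_low_int_high: Sequence[float], anova: TestResult, q_cut: float = 0.05
) -> bool:
    """True iff the ANOVA survives FDR and the tertile means increase
    strictly from low to intermediate to high."""
    lo, mid, hi = means_low_int_high
    return bool(anova.q_value < q_cut and lo < mid < hi)


def _vector_t(
    x_a: np.ndarray, x_b: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise pooled t-test of b vs a; returns (t, p, mean_a, mean_b)."""
    res = stats.ttest_ind(x_b, x_a, axis=1, equal_var=not welch, nan_policy="omit")
    mean_a = np.nanmean(x_a, axis=1)
    mean_b = np.nanmean(x_b, axis=1)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance rows: scipy yields nan; equal means -> t=0,p=1, else p=0
    bad = ~np.isfinite(p)
    if bad.any():
        eq = np.isclose(mean_a, mean_b)
        t = np.where(bad & eq, 0.0, t)
        p = np.where(bad & eq, 1.0, p)
        p = np.where(bad & ~eq, 0.0, p)
    return t, p, mean_a, mean_b


def run_screen(
    expr: ExpressionMatrix,
    annotation: CohortAnnotation,
    aggressiveness: pd.Series,
    survival_flags: Mapping[str, str] | pd.Series,
    q_cut: float = 0.05,
    surv_p_cut: float | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Run all four criteria for every gene and intersect the flags.

    ``aggressiveness`` maps tumor sample ids to low/intermediate/high;
    ``survival_flags`` maps genes to poor_survival/good_survival/none (from
    :func:`oncoscreen.survival_analysis.best_cutoff_table`; if that table
    was built with a different p cutoff pass the table and ``surv_p_cut``
    has no effect here). Returns one row per gene with statistics, three
    independent BH families of q-values, the four flags, and the combined
    ``oncogenic_target`` call.
    """
    strata = {
        "tumor": annotation.tumors,
        "normal": annotation.normals,
        "early-stage": annotation.samples_with_stage("early"),
        "advanced-stage": annotation.samples_with_stage("advanced"),
    }
    agg = pd.Series(aggressiveness)
    for label in ("low", "intermediate", "high"):
        strata[f"{label}-aggressiveness"] = list(agg.index[agg == label])
    empty = [name for name, ids in strata.items() if len(ids) == 0]
    if empty:
        raise DataError(f"empty stratum: {', '.join(empty)}")

    genes = expr.feature_ids
    x = {name: expr.subset_samples(ids).values for name, ids in strata.items()}

    # 1) normal vs tumor
    t1, p1, mean_n, mean_t = _vector_t(x["normal"], x["tumor"], welch)
    q1 = bh_adjust(p1)
    up_in_tumor = (q1 < q_cut) & (mean_t > mean_n)

    # 2) among aggressiveness tertiles
    res2 = stats.f_oneway(
        x["low-aggressiveness"],
        x["intermediate-aggressiveness"],
        x["high-aggressiveness"],
        axis=1,
    )
    f2 = np.asarray(res2.statistic, dtype=float)
    p2 = np.asarray(res2.pvalue, dtype=float)
    m_lo = np.nanmean(x["low-aggressiveness"], axis=1)
    m_mid = np.nanmean(x["intermediate-aggressiveness"], axis=1)
    m_hi = np.nanmean(x["high-aggressiveness"], axis=1)
    flat = ~np.isfinite(p2)
    if flat.any():
        eq = np.isclose(m_lo, m_mid) & np.isclose(m_mid, m_hi)
        f2 = np.where(flat & eq, 0.0, f2)
        p2 = np.where(flat & eq, 1.0, p2)
        p2 = np.where(flat & ~eq, 0.0, p2)
    q2 = bh_adjust(p2)
    successive = (q2 < q_cut) & (m_lo < m_mid) & (m_mid < m_hi)

    # 3) early vs advanced stage
    t3, p3, mean_e, mean_a = _vector_t(x["early-stage"], x["advanced-stage"], welch)
    q3 = bh_adjust(p3)
    up_in_advanced = (q3 < q_cut) & (mean_a > mean_e)

    # 4) poor survival at the best cutoff
    sflags = pd.Series(survival_flags)
    poor = np.array([sflags.get(g, "none") == "poor_survival" for g in genes])

    out = pd.DataFrame(
        {
            "t_tumor_vs_normal": t1,
            "p_tumor_vs_normal": p1,
            "q_tumor_vs_normal": q1,
            "mean_normal": mean_n,
            "mean_tumor": mean_t,
            "f_aggressiveness": f2,
            "p_aggressiveness": p2,
            "q_aggressiveness": q2,
            "mean_low": m_lo,
            "mean_intermediate": m_mid,
            "mean_high": m_hi,
            "t_advanced_vs_early": t3,
            "p_advanced_vs_early": p3,
            "q_advanced_vs_early": q3,
            "mean_early": mean_e,
            "mean_advanced": mean_a,
            "up_in_tumor": up_in_tumor,
            "successive_up": successive,
            "up_in_advanced": up_in_advanced,
            "poor_survival": poor,
        },
        index=pd.Index(genes, name="gene"),
    )
    out["oncogenic_target"] = out[list(FLAG_COLUMNS)].all(axis=1)
    log.info(
        "screen: %d/%d genes pass all four criteria", int(out["oncogenic_target"].sum()), len(out)
    )
    return out


def venn_counts(screen: pd.DataFrame) -> pd.DataFrame:
    """Counts over the 16 flag combinations; the all-True cell is the
    oncogenic-target count."""
    combos = list(product((False, True), repeat=4))
    rows = []
    flags = screen[list(FLAG_COLUMNS)]
    for combo in combos:
        mask = np.ones(len(flags), dtype=bool)
        for col, val in zip(FLAG_COLUMNS, combo):
            mask &= flags[col].to_numpy() == val
        rows.append((*combo, int(mask.sum())))
    return pd.DataFrame(rows, columns=[*FLAG_COLUMNS, "count"])
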