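"""Gene set enrichment: weighted-KS GSEA and hypergeometric over-representation.

GSEA here is the classical two-class procedure: genes are ranked by a
signal-to-noise metric between two phenotype classes, a weighted
Kolmogorov-Smirnov running sum is walked down the ranked list (hits add
|metric|^p normalized by the in-set total, misses subtract 1/(N - N_hits)),
and the enrichment score (ES) is the signed maximum deviation. Nominal p
and the normalized enrichment score (NES) come from a permutation null —
either random gene sets of matched size ("gene_set") or phenotype-label
permutations ("phenotype") — and FDR q follows the permutation-ratio
procedure: the fraction of permutation NES at least as extreme as a set's
NES divided by the fraction of observed NES at least as extreme, computed
separately for positive and negative scores and capped at 1.

Over-representation (the functional-annotation stand-in) is the upper-tail
hypergeometric test, optionally with the conservative EASE variant that
discounts one gene from the overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, UndefinedStatisticError
from .types import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "GSEAResult",
    "ORAResult",
    "rank_by_signal_to_noise",
    "enrichment_score",
    "gsea",
    "ora_test",
]


@dataclass(frozen=True)
class RankedList:
    """Features ordered best-to-worst with their ranking metric."""

    feature_ids: tuple[str, ...]
    metric_values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(set(self.feature_ids)):
            raise DataError("ranked list has duplicate feature ids")
        m = np.asarray(self.metric_values, dtype=float)
        if np.any(np.diff(m) > 0):
            raise DataError("metric values must be non-increasing")
        object.__setattr__(self, "metric_values", m)

    def __len__(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class GSEAResult:
    gene_set: str
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    n_permutations: int
    leading_edge: tuple[str, ...]
    p_is_upper_bound: bool = False  # True when no permutation was as extreme


@dataclass(frozen=True)
class ORAResult:
    gene_set: str
    overlap: int  # k
    query_size: int  # n
    set_size: int  # K
    universe_size: int  # N
    p_value: float
    fold_enrichment: float
    ease: bool = False


def _s2n_sigma(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class mean and floored SD per the GSEA signal-to-noise convention:
    sd is floored at 0.2*|mean| (0.2 when the mean is zero)."""
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    floor = 0.2 * np.abs(mu)
    floor = np.where(floor == 0, 0.2, floor)
    return mu, np.maximum(sd, floor)


def _s2n_metric(x_pos: np.ndarray, x_neg: np.ndarray) -> np.ndarray:
    mu_p, sd_p = _s2n_sigma(x_pos)
    mu_n, sd_n = _s2n_sigma(x_neg)
    return (mu_p - mu_n) / (sd_p + sd_n)


def rank_by_signal_to_noise(
    expr: ExpressionMatrix,
    phenotype: pd.Series,
    positive_class: str = "high",
) -> RankedList:
    """Rank genes by signal-to-noise between the two phenotype classes.

    Positive metric = higher in ``positive_class``. Descending sort, ties
    broken by feature id.
    """
    phen = pd.Series(phenotype)
    classes = [c for c in pd.unique(phen) if pd.notna(c)]
    if len(classes) != 2:
        raise DataError(f"phenotype must have exactly 2 classes, got {classes}")
    if positive_class not in classes:
        raise ConfigurationError(f"positive_class {positive_class!r} not among {classes}")
    negative_class = next(c for c in classes if c != positive_class)
    pos_ids = list(phen.index[phen == positive_class])
    neg_ids = list(phen.index[phen == negative_class])
    if len(pos_ids) < 2 or len(neg_ids) < 2:
        raise DataError("each phenotype class needs at least 2 samples")
    metric = _s2n_metric(
        expr.subset_samples(pos_ids).values, expr.subset_samples(neg_ids).values
    )
    order = np.lexsort((np.asarray(expr.feature_ids), -metric))
    return RankedList(
        feature_ids=tuple(np.asarray(expr.feature_ids)[order]),
        metric_values=metric[order],
    )


def _es_from_hits(
    metric: np.ndarray, hit: np.ndarray, weight: float
) -> tuple[float, np.ndarray, int]:
    """Weighted-KS running sum; returns (es, running_sum, extremum index)."""
    n = metric.size
    nh = int(hit.sum())
    if nh == 0 or nh == n:
        raise UndefinedStatisticError("gene set covers none or all of the ranked list")
    w = np.abs(metric) ** weight if weight != 0 else np.ones(n)
    hw = np.where(hit, w, 0.0)
    total = hw.sum()
    if total == 0:  # every in-set metric is exactly zero: fall back to equal hits
        hw = hit.astype(float)
        total = float(nh)
    steps = hw / total - (~hit) / (n - nh)
    running = np.cumsum(steps)
    # signed maximum deviation; an exact magnitude tie between the positive
    # and negative extremum resolves to the positive one
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min] - 1e-12:
        idx = i_max
    else:
        idx = i_min
    return float(running[idx]), running, idx


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight: float = 1.0
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """ES, running sum, and leading edge of ``gene_set`` on ``ranked``.

    The leading edge contains the set members at or before the maximum for
    a positive ES, and at or after the minimum for a negative ES.
    """
    members = set(gene_set.members)
    ids = np.asarray(ranked.feature_ids)
    hit = np.isin(ids, list(members))
    es, running, idx = _es_from_hits(ranked.metric_values, hit, weight)
    if es >= 0:
        leading = tuple(ids[: idx + 1][hit[: idx + 1]])
    else:
        leading = tuple(ids[idx:][hit[idx:]])
    return es, running, leading


def gsea(
    expr: ExpressionMatrix,
    phenotype: pd.Series,
    gene_sets: Sequence[GeneSet],
    n_perm: int = 1000,
    perm_type: str = "gene_set",
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    positive_class: str = "high",
    seed: int | None = None,
) -> list[GSEAResult]:
    """Permutation GSEA over a collection of gene sets.

    Sets are filtered to [min_size, max_size] members present in the
    matrix. ``perm_type`` is either "gene_set" (size-matched random sets;
    robust at small class sizes) or "phenotype" (label permutation with
    re-ranking). Seeded and reproducible.
    """
    if perm_type not in ("gene_set", "phenotype"):
        raise ConfigurationError(f"unknown perm_type {perm_type!r}")
    if n_perm < 100:
        log.warning("n_perm=%d is low; p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    ranked = rank_by_signal_to_noise(expr, phenotype, positive_class=positive_class)
    ids = np.asarray(ranked.feature_ids)
    n = ids.size
    present: list[tuple[GeneSet, np.ndarray]] = []
    for gs in gene_sets:
        hit = np.isin(ids, list(set(gs.members)))
        k = int(hit.sum())
        if min_size <= k <= max_size and k < n:
            present.append((gs, hit))
        else:
            log.info("gsea: set %s filtered (size %d outside [%d, %d])", gs.name, k, min_size, max_size)
    if not present:
        raise DataError("no gene set within the size bounds after intersection")

    observed = []
    for gs, hit in present:
        es, _, leading = enrichment_score(ranked, gs, weight)
        observed.append((gs, hit, es, leading))

    # permutation ES, one row per permutation per set
    perm_es = np.empty((len(present), n_perm))
    if perm_type == "gene_set":
        for j, (gs, hit, _, _) in enumerate(observed):
            k = int(hit.sum())
            for b in range(n_perm):
                rnd = np.zeros(n, dtype=bool)
                rnd[rng.choice(n, size=k, replace=False)] = True
                perm_es[j, b], _, _ = _es_from_hits(ranked.metric_values, rnd, weight)
    else:
        phen = pd.Series(phenotype)
        labels = phen.to_numpy()
        sample_ids = list(phen.index)
        sub = expr.subset_samples(sample_ids)
        values = sub.values
        feature_arr = np.asarray(sub.feature_ids)
        member_masks = [np.isin(feature_arr, list(set(gs.members))) for gs, _, _, _ in observed]
        pos_label = positive_class
        for b in range(n_perm):
            perm = rng.permutation(labels)
            pos = perm == pos_label
            metric = _s2n_metric(values[:, pos], values[:, ~pos])
            order = np.lexsort((feature_arr, -metric))
            metric_sorted = metric[order]
            for j, mask in enumerate(member_masks):
                perm_es[j, b], _, _ = _es_from_hits(metric_sorted, mask[order], weight)

    results: list[GSEAResult] = []
    obs_es = np.array([es for _, _, es, _ in observed])
    # per-set normalization by the mean magnitude of same-sign permutation ES
    pos_means = np.array(
        [row[row > 0].mean() if (row > 0).any() else np.nan for row in perm_es]
    )
    neg_means = np.array(
        [(-row[row < 0]).mean() if (row < 0).any() else np.nan for row in perm_es]
    )
    obs_nes = np.where(obs_es >= 0, obs_es / pos_means, obs_es / neg_means)
    with np.errstate(invalid="ignore", divide="ignore"):
        perm_nes = np.where(perm_es >= 0, perm_es / pos_means[:, None], perm_es / neg_means[:, None])
    perm_nes_flat = perm_nes[np.isfinite(perm_nes)]

    for j, (gs, hit, es, leading) in enumerate(observed):
        row = perm_es[j]
        same_sign = row >= 0 if es >= 0 else row < 0
        n_same = int(same_sign.sum())
        upper_bound = False
        if n_same == 0:
            p = 1.0 / n_perm
            upper_bound = True
            nes = float("nan")
        else:
            extreme = np.abs(row[same_sign]) >= abs(es)
            p = float(extreme.mean())
            nes = float(obs_nes[j])
        # FDR q: permutation-ratio on the NES scale
        if np.isfinite(nes):
            if nes >= 0:
                num_pool = perm_nes_flat[perm_nes_flat >= 0]
                num = (num_pool >= nes).mean() if num_pool.size else 0.0
                obs_pool = obs_nes[np.isfinite(obs_nes) & (obs_nes >= 0)]
                den = (obs_pool >= nes).mean() if obs_pool.size else 1.0
            else:
                num_pool = perm_nes_flat[perm_nes_flat < 0]
                num = (num_pool <= nes).mean() if num_pool.size else 0.0
                obs_pool = obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)]
                den = (obs_pool <= nes).mean() if obs_pool.size else 1.0
            q = min(1.0, num / den) if den > 0 else 1.0
        else:
            q = float("nan")
        results.append(
            GSEAResult(
                gene_set=gs.name,
                es=float(es),
                nes=nes,
                nominal_p=float(p),
                fdr_q=float(q),
                n_permutations=n_perm,
                leading_edge=leading,
                p_is_upper_bound=upper_bound,
            )
        )
    return results


def ora_test(
    query: GeneSet, annotation_set: GeneSet, universe: GeneSet, ease: bool = False
) -> ORAResult:
    """Upper-tail hypergeometric over-representation test.

    With ``ease`` the overlap is discounted by one gene (the conservative
    EASE score used by functional-annotation servers); an empty overlap
    under EASE returns p=1.
    """
    uni = set(universe.members)
    q = set(query.members) & uni
    s = set(annotation_set.members) & uni
    if len(q) < len(set(query.members)) or len(s) < len(set(annotation_set.members)):
        log.info(
            "ora: query/set members outside the universe were dropped (%s vs %s)",
            query.name,
            annotation_set.name,
        )
    big_n, big_k, n = len(uni), len(s), len(q)
    k = len(q & s)
    if ease:
        k_eff = k - 1
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k_eff - 1, big_n, big_k, n))
    else:
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    fold = (k / n) / (big_k / big_n) if n > 0 and big_k > 0 else float("nan")
    return ORAResult(
        gene_set=annotation_set.name,
        overlap=k,
        query_size=n,
        set_size=big_k,
        universe_size=big_n,
        p_value=p,
        fold_enrichment=float(fold),
        ease=ease,
    )
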