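"""Correlation screens: miRNA suppressor ranking, signature-signature
correlation, dependency-score summaries, and TF target-coverage reports.

Candidate suppressor miRNAs are ranked by the arithmetic mean of their
Pearson correlations against each gene of a signature (most negative mean
first); a rank-sum aggregate is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .signature_scoring import SignatureScore, scores_as_series
from .types import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "RegulatorRanking",
    "pearson",
    "rank_negative_regulators",
    "signature_correlation",
    "summarize_dependency",
    "tf_consistency_report",
    "common_regulators",
]


@dataclass(frozen=True)
class CorrelationResult:
    id_a: str
    id_b: str
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class RegulatorRanking:
    """Ranked miRNA table (ascending mean r) plus the per-gene r matrix."""

    table: pd.DataFrame  # index mirna, columns mean_r, rank
    per_gene_r: pd.DataFrame  # mirna x signature gene
    top: tuple[str, ...]


def pearson(
    x: Sequence[float], y: Sequence[float], id_a: str = "x", id_b: str = "y"
) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-transform p
    (n-2 df). Missing values are dropped pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("paired vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DataError("Pearson correlation needs at least 3 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(id_a, id_b, float(res.statistic), float(res.pvalue), int(x.size))


def _pairwise_r(mirna_values: np.ndarray, gene_values: np.ndarray) -> np.ndarray:
    """Correlation matrix (miRNAs x genes) over shared samples, vectorized."""
    m = mirna_values - mirna_values.mean(axis=1, keepdims=True)
    g = gene_values - gene_values.mean(axis=1, keepdims=True)
    m_sd = np.sqrt((m**2).sum(axis=1))
    g_sd = np.sqrt((g**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (m @ g.T) / np.outer(m_sd, g_sd)
    return r


def rank_negative_regulators(
    mirna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    signature: GeneSet,
    top_k: int = 2,
    min_shared: int = 10,
    min_detection: float = 0.2,
    aggregate: str = "mean",
) -> RegulatorRanking:
    """Rank miRNAs by how negatively they correlate with a gene signature.

    Correlations are computed on the samples shared by both matrices;
    miRNAs with zero variance or detected (value > 0) in fewer than
    ``min_detection`` of shared samples are excluded. ``aggregate`` is
    "mean" (arithmetic mean of per-gene r) or "rank_sum" (sum of each
    miRNA's rank across genes; more robust to a single extreme gene).
    """
    if aggregate not in ("mean", "rank_sum"):
        raise ConfigurationError(f"unknown aggregate {aggregate!r}")
    shared = [s for s in mirna_expr.sample_ids if s in set(gene_expr.sample_ids)]
    if len(shared) < min_shared:
        raise DataError(
            f"only {len(shared)} shared samples between matrices (need >= {min_shared})"
        )
    present = signature.intersect(gene_expr.feature_ids)
    if not present:
        raise DataError(f"no member of {signature.name!r} in the gene matrix")
    mir = mirna_expr.subset_samples(shared)
    genes = gene_expr.subset_samples(shared).subset_features(list(present))

    mvals = mir.values
    variance = mvals.var(axis=1, ddof=1)
    detection = (mvals > 0).mean(axis=1)
    keep = (variance > 0) & (detection >= min_detection)
    dropped = int((~keep).sum())
    if dropped:
        log.info("miRNA ranking: excluded %d low-expression/zero-variance miRNAs", dropped)
    if not keep.any():
        raise DataError("no miRNA passes the expression filter")
    mir_ids = np.asarray(mir.feature_ids)[keep]
    r = _pairwise_r(mvals[keep], genes.values)
    per_gene = pd.DataFrame(r, index=pd.Index(mir_ids, name="mirna"), columns=list(present))
    mean_r = per_gene.mean(axis=1)
    if aggregate == "mean":
        key = mean_r
    else:
        key = per_gene.rank(axis=0).sum(axis=1)
    order = key.sort_values(kind="mergesort").index  # ascending: most negative first
    table = pd.DataFrame({"mean_r": mean_r.loc[order]})
    table["rank"] = np.arange(1, len(table) + 1)
    return RegulatorRanking(
        table=table, per_gene_r=per_gene.loc[order], top=tuple(order[:top_k])
    )


def signature_correlation(
    scores_a: Sequence[SignatureScore], scores_b: Sequence[SignatureScore],
    name_a: str = "signature_a", name_b: str = "signature_b",
) -> CorrelationResult:
    """Pearson correlation between two signature scores on shared samples."""
    a = scores_as_series(scores_a)
    b = scores_as_series(scores_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise DataError("fewer than 3 shared samples between score lists")
    return pearson(a.loc[shared], b.loc[shared], name_a, name_b)


def summarize_dependency(chronos: pd.DataFrame, signature: GeneSet) -> pd.Series:
    """Mean CRISPR dependency (chronos) score over a gene set, per cell line.

    ``chronos`` is genes x cell lines; more negative means more essential.
    The returned Series carries the per-cell-line means, with the grand
    mean under ``.attrs['overall_mean']`` and any absent signature genes
    under ``.attrs['missing_genes']``.
    """
    present = signature.intersect(chronos.index)
    if not present:
        raise DataError(f"no member of {signature.name!r} in the dependency table")
    missing = [m for m in signature.members if m not in set(present)]
    if missing:
        log.info("dependency summary: %d signature genes missing from table", len(missing))
    summary = chronos.loc[list(present)].mean(axis=0)
    summary.name = f"{signature.name}_dependency"
    summary.attrs["overall_mean"] = float(summary.mean())
    summary.attrs["missing_genes"] = tuple(missing)
    return summary


def tf_consistency_report(
    predictions: pd.DataFrame,
    signature: GeneSet,
    mirnas: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-TF fraction of signature genes (and of listed miRNAs) predicted
    as targets. Empty predictions yield zero coverage."""
    sig = set(signature.members)
    mirs = {m.lower() for m in mirnas}
    if predictions.shape[0] == 0:
        return pd.DataFrame(columns=["gene_coverage", "mirna_coverage"])
    rows = {}
    for tf, grp in predictions.groupby("regulator_id"):
        targets = set(grp["target_id"])
        targets_lower = {t.lower() for t in targets}
        rows[tf] = {
            "gene_coverage": len(targets & sig) / len(sig) if sig else 0.0,
            "mirna_coverage": len(targets_lower & mirs) / len(mirs) if mirs else 0.0,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "tf"
    return out.sort_values(["gene_coverage", "mirna_coverage"], ascending=False)


def common_regulators(predictions: pd.DataFrame, targets: Sequence[str]) -> set[str]:
    """TFs predicted to regulate every listed target (Venn intersection)."""
    sets = []
    lower_map = predictions.assign(_t=predictions["target_id"].str.lower())
    for t in targets:
        sets.append(set(lower_map.loc[lower_map["_t"] == t.lower(), "regulator_id"]))
    return set.intersection(*sets) if sets else set()
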