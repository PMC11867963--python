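"""Z-score signature scoring and group splits.

A signature score for a patient is the plain sum of per-gene expression
z-scores over the members of a gene set — the same construction is used for
the tumor-aggressiveness (EMT) score and for downstream hub/miRNA/TF
signature scores. Patients are stratified either into tertiles
(low/intermediate/high aggressiveness) or by a median split (low/high).

Z-scores are computed over the sample subset that enters the comparison
(e.g. tumors only for aggressiveness tertiles) so that normal samples do
not dominate the standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .types import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "SignatureScore",
    "zscore_matrix",
    "signature_score",
    "scores_as_series",
    "tertile_groups",
    "median_split",
]


@dataclass(frozen=True)
class SignatureScore:
    sample_id: str
    score: float
    coverage: float  # fraction of signature members present in the matrix


def zscore_matrix(
    expr: ExpressionMatrix, sample_subset: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Per-gene z-scores over a sample subset (sample SD, n-1 denominator).

    Zero-variance genes emit z=0 for all samples and are recorded in the
    ``zero_variance`` field of the returned matrix.
    """
    sub = expr if sample_subset is None else expr.subset_samples(sample_subset)
    if sub.n_samples < 2:
        raise DataError("z-scoring needs at least 2 samples")
    values = sub.values
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    flat = (sd == 0) | ~np.isfinite(sd)
    sd_safe = np.where(flat, 1.0, sd)
    z = (values - mean) / sd_safe
    z[flat[:, 0], :] = 0.0
    flagged = tuple(np.asarray(sub.feature_ids)[flat[:, 0]])
    if flagged:
        log.info("z-scoring: %d zero-variance genes set to 0", len(flagged))
    data = pd.DataFrame(z, index=sub.data.index, columns=sub.data.columns)
    return replace(sub, data=data, zero_variance=flagged)


def signature_score(zscores: ExpressionMatrix, gene_set: GeneSet) -> list[SignatureScore]:
    """Per-sample sum of z-scores over the present members of ``gene_set``."""
    present = gene_set.intersect(zscores.feature_ids)
    if not present:
        raise DataError(f"no member of {gene_set.name!r} present in matrix")
    absent = [m for m in gene_set.members if m not in set(present)]
    if absent:
        log.info("signature %s: %d members absent from matrix", gene_set.name, len(absent))
    coverage = len(present) / len(gene_set)
    totals = zscores.data.loc[list(present)].sum(axis=0)
    return [
        SignatureScore(sample_id=s, score=float(totals[s]), coverage=coverage)
        for s in zscores.sample_ids
    ]


def scores_as_series(scores: Sequence[SignatureScore]) -> pd.Series:
    return pd.Series({s.sample_id: s.score for s in scores}, name="score")


def _sorted_ids(scores: Sequence[SignatureScore]) -> list[str]:
    # ascending score; ties broken by sample_id so assignment is deterministic
    return [s.sample_id for s in sorted(scores, key=lambda s: (s.score, s.sample_id))]


def tertile_groups(scores: Sequence[SignatureScore]) -> pd.Series:
    """Low / intermediate / high tertiles by ascending score.

    Group sizes differ by at most one; any remainder is assigned low-first
    (n=10 -> 4/3/3).
    """
    n = len(scores)
    if n < 3:
        raise DataError("tertile split needs at least 3 samples")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    ordered = _sorted_ids(scores)
    labels: dict[str, str] = {}
    bounds = np.cumsum([0] + sizes)
    for label, lo, hi in zip(("low", "intermediate", "high"), bounds[:-1], bounds[1:]):
        for sid in ordered[lo:hi]:
            labels[sid] = label
    return pd.Series(labels, name="group")


def median_split(scores: Sequence[SignatureScore]) -> pd.Series:
    """Equal-size low/high split by ascending score; odd n puts the extra
    sample in the low group."""
    n = len(scores)
    if n < 2:
        raise DataError("median split needs at least 2 samples")
    n_low = n - n // 2
    ordered = _sorted_ids(scores)
    labels = {sid: ("low" if i < n_low else "high") for i, sid in enumerate(ordered)}
    return pd.Series(labels, name="group")
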