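"""Core in-memory containers shared by every pipeline stage.

The containers are thin wrappers around :class:`pandas.DataFrame` — the
field's canonical tabular carrier — plus light invariant checks:

* :class:`ExpressionMatrix` — features (genes or miRNAs) x samples.
* :class:`CohortAnnotation` — one clinical record per sample.
* :class:`GeneSet` — a named, de-duplicated collection of feature symbols.

Interaction tables (miRNA->gene, TF->gene/miRNA, STRING edges) are plain
DataFrames with the columns ``regulator_id``, ``target_id``, ``score``,
``source``; see :func:`interaction_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "ExpressionMatrix",
    "CohortAnnotation",
    "GeneSet",
    "interaction_table",
    "INTERACTION_COLUMNS",
    "INTERACTION_SOURCES",
]

INTERACTION_COLUMNS = ("regulator_id", "target_id", "score", "source")
INTERACTION_SOURCES = ("mirdip", "transmir", "htftarget", "string")

ANNOTATION_COLUMNS = (
    "tissue",
    "stage",
    "grade",
    "invasiveness",
    "progression",
    "survival_time",
    "survival_event",
    "endpoint",
)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features x samples numeric matrix.

    ``data`` is indexed by feature symbol with sample identifiers as columns.
    ``transformed`` records whether values are log2(x+1)-transformed.
    ``zero_variance`` lists features flagged during z-scoring.
    """

    data: pd.DataFrame
    transformed: bool = False
    zero_variance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate feature identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise DataError("duplicate sample identifiers")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataError(f"samples not in matrix: {missing[:5]}")
        return replace(self, data=self.data.loc[:, list(sample_ids)])

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise DataError(f"features not in matrix: {missing[:5]}")
        return replace(self, data=self.data.loc[list(feature_ids)])


@dataclass(frozen=True)
class CohortAnnotation:
    """Per-sample clinical annotation.

    ``table`` is indexed by sample_id with the columns ``tissue``
    ({normal, tumor}), ``stage`` ({early, advanced, unknown}), ``grade``
    ({low, high, unknown}), ``invasiveness`` ({non_muscle_invasive,
    muscle_invasive, unknown}), ``progression`` (ordinal or NaN),
    ``survival_time`` (days), ``survival_event`` (0 censored / 1 death) and
    ``endpoint`` ({overall, cancer_specific}).

    Samples lacking survival time or event are retained but excluded from
    survival analyses (see :meth:`survival_subset`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ANNOTATION_COLUMNS:
            if col not in self.table.columns:
                raise DataError(f"annotation missing column {col!r}")
        t = self.table["survival_time"]
        if (t.dropna() < 0).any():
            raise DataError("negative survival_time")
        ev = self.table["survival_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise DataError("survival_event must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_with_tissue(self, tissue: str) -> list[str]:
        return list(self.table.index[self.table["tissue"] == tissue])

    @property
    def tumors(self) -> list[str]:
        return self.samples_with_tissue("tumor")

    @property
    def normals(self) -> list[str]:
        return self.samples_with_tissue("normal")

    def samples_with_stage(self, stage: str) -> list[str]:
        return list(self.table.index[self.table["stage"] == stage])

    def survival_subset(self, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Rows with both survival time and event; others are excluded."""
        tab = self.table if sample_ids is None else self.table.loc[list(sample_ids)]
        ok = tab["survival_time"].notna() & tab["survival_event"].notna()
        return tab.loc[ok]

    @property
    def excluded_from_survival(self) -> list[str]:
        tab = self.table
        bad = tab["survival_time"].isna() | tab["survival_event"].isna()
        return list(tab.index[bad])


@dataclass(frozen=True)
class GeneSet:
    """A named collection of feature symbols (GMT-derived or pipeline-derived)."""

    name: str
    description: str
    members: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise DataError(f"gene set {self.name!r} has no members")
        # de-duplicate preserving order
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m, None)
        object.__setattr__(self, "members", tuple(seen))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in set(self.members)

    def intersect(self, features: Iterable[str]) -> tuple[str, ...]:
        present = set(features)
        return tuple(m for m in self.members if m in present)


def interaction_table(
    rows: Iterable[tuple[str, str, float]] | pd.DataFrame,
    source: str,
) -> pd.DataFrame:
    """Normalize interaction rows to the standard four-column DataFrame."""
    from .errors import ConfigurationError

    if source not in INTERACTION_SOURCES:
        raise ConfigurationError(
            f"unknown interaction source {source!r}; expected one of {INTERACTION_SOURCES}"
        )
    if isinstance(rows, pd.DataFrame):
        df = rows.loc[:, ["regulator_id", "target_id", "score"]].copy()
    else:
        df = pd.DataFrame(list(rows), columns=["regulator_id", "target_id", "score"])
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    if df["score"].notna().any() and not np.isfinite(df["score"].dropna()).all():
        raise DataError("non-finite interaction scores")
    df["source"] = source
    if source == "mirdip":
        # miRNA regulator names follow miRBase lower-case convention
        df["regulator_id"] = df["regulator_id"].str.lower()
        self_pairs = df["regulator_id"].str.upper() == df["target_id"].str.upper()
        df = df.loc[~self_pairs]
    return df.reset_index(drop=True)
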