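"""Readers and writers for the pipeline's text formats.

Supported dialects:

* Firehose-style expression matrices (tab-separated, composite
  ``SYMBOL|entrez`` identifiers in the first column, TCGA barcodes as
  column headers),
* GEO series-matrix text (``!``-prefixed metadata, probe table between
  begin/end markers),
* GMT gene-set files,
* STRING-style edge lists,
* generic regulator->target prediction tables (mirDIP / TransmiR /
  hTFtarget exports).

All writers emit tab-separated text with a header row so that every matrix
round-trips through its own reader.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import BarcodeError, ConfigurationError, FormatError, ParseError
from .types import CohortAnnotation, ExpressionMatrix, GeneSet, interaction_table
from .types import ANNOTATION_COLUMNS

log = logging.getLogger(__name__)

__all__ = [
    "read_firehose_matrix",
    "write_firehose_matrix",
    "parse_tcga_barcode",
    "annotation_from_barcodes",
    "read_geo_series_matrix",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_prediction_table",
    "read_annotation",
    "write_annotation",
    "collapse_duplicate_features",
]


def collapse_duplicate_features(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate feature rows, keeping the row with the highest mean.

    Idempotent; ties broken by first occurrence in file order.
    """
    if not df.index.has_duplicates:
        return df
    pos = pd.DataFrame(
        {
            "symbol": df.index.to_numpy(),
            "pos": np.arange(len(df)),
            "mean": df.mean(axis=1, skipna=True).to_numpy(),
        }
    )
    chosen = (
        pos.sort_values(["mean", "pos"], ascending=[False, True])
        .drop_duplicates(subset="symbol", keep="first")["pos"]
        .to_numpy()
    )
    return df.iloc[np.sort(chosen)]


def _read_table_text(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    return df


def _to_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except ValueError:
        pass
    # locate the offending cell for the error message
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].str.strip().str.upper() != "NA")
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
    # only NA-like strings: coerce quietly to NaN
    return df.apply(pd.to_numeric, errors="coerce")


def read_firehose_matrix(path: str | Path, log_transform: bool = True) -> ExpressionMatrix:
    """Read a Firehose-preprocessed expression matrix.

    The first column holds composite ``SYMBOL|entrez`` identifiers; rows
    whose symbol is ``?`` are dropped, duplicate symbols are collapsed to
    the highest-mean row, and values are log2(x+1)-transformed when
    ``log_transform`` is set.
    """
    df = _read_table_text(path)
    df = _to_numeric(df, path)
    symbols = [str(ix).split("|", 1)[0] for ix in df.index]
    df.index = pd.Index(symbols, name="symbol")
    df = df.loc[df.index != "?"]
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no named features after dropping '?' rows")
    df = collapse_duplicate_features(df)
    if log_transform:
        if (df < 0).any().any():
            raise FormatError(f"{path}: negative values cannot be log2(x+1)-transformed")
        df = np.log2(df + 1.0)
    return ExpressionMatrix(data=df, transformed=log_transform)


def write_firehose_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the composite-identifier dialect (entrez slot = 0)."""
    df = matrix.data.copy()
    df.index = pd.Index([f"{s}|0" for s in df.index], name="gene_id")
    df.to_csv(path, sep="\t", float_format="%.10g")


_SAMPLE_TYPE_TUMOR = range(1, 10)
_SAMPLE_TYPE_NORMAL = range(10, 20)


def parse_tcga_barcode(barcode: str) -> dict[str, str]:
    """Split a TCGA barcode into patient id and tissue type.

    Sample-type codes 01-09 are tumors, 10-19 normals (GDC convention).
    """
    fields = barcode.split("-")
    if len(fields) < 4:
        raise BarcodeError(f"barcode {barcode!r} has fewer than 4 dash-separated fields")
    code_txt = fields[3][:2]
    if not code_txt.isdigit():
        raise BarcodeError(f"barcode {barcode!r}: sample-type code {code_txt!r} not numeric")
    code = int(code_txt)
    if code in _SAMPLE_TYPE_TUMOR:
        tissue = "tumor"
    elif code in _SAMPLE_TYPE_NORMAL:
        tissue = "normal"
    else:
        raise BarcodeError(f"barcode {barcode!r}: sample-type code {code:02d} out of range 01-19")
    return {"patient_id": "-".join(fields[:3]), "tissue": tissue}


def annotation_from_barcodes(barcodes: Sequence[str]) -> pd.DataFrame:
    """Tissue assignment table for a set of barcodes (tumor/normal partition)."""
    rows = {b: parse_tcga_barcode(b) for b in barcodes}
    return pd.DataFrame.from_dict(rows, orient="index")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: per line, name, description, then >=1 member."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, *members = parts
            members = [m for m in members if m]
            sets.append(GeneSet(name=name, description=desc, members=tuple(members)))
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_edge_list(path: str | Path, min_score: float = 0.0) -> nx.Graph:
    """Read an undirected weighted edge list (STRING export dialect accepted).

    Edges below ``min_score`` are dropped (their endpoints are kept as
    isolated nodes), self-loops removed, and duplicate edges merged keeping
    the maximum score. Scores on the STRING 0-999 integer scale are
    normalized to (0, 1].
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing file: {path}")
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        first = fh.readline()
        sep = "\t" if "\t" in first else None  # STRING exports are space-separated
        header = first.split(sep)
        has_header = not _is_number(header[-1])
        if not has_header:
            fh.seek(0)
        for lineno, line in enumerate(fh, start=2 if has_header else 1):
            parts = line.split(sep)
            if len(parts) < 3 or not line.strip():
                continue
            a, b, s = parts[0].strip(), parts[1].strip(), parts[2].strip()
            try:
                score = float(s)
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric score {s!r} at line {lineno}") from exc
            if score < 0:
                raise FormatError(f"{path}: negative score {score} at line {lineno}")
            rows.append((a, b, score))
    if not rows:
        raise FormatError(f"{path}: no edges found")
    scale = 1000.0 if max(r[2] for r in rows) > 1.0 else 1.0
    graph = nx.Graph()
    for a, b, score in rows:
        score /= scale
        graph.add_node(a)
        graph.add_node(b)
        if a == b or score < min_score:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["weight"] = max(graph[a][b]["weight"], score)
        else:
            graph.add_edge(a, b, weight=score)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):.6g}\n")
        # isolated nodes as self-referential zero rows are NOT written; they
        # are recorded separately by callers that need them.


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# column-name dialects per prediction source
_PREDICTION_DIALECTS: dict[str, dict[str, tuple[str, ...]]] = {
    "mirdip": {
        "regulator": ("MicroRNA", "miRNA", "microrna", "mirna"),
        "target": ("Gene Symbol", "GeneSymbol", "Gene", "gene_symbol", "gene"),
        "score": ("Integrated Score", "Score", "integrated_score", "score"),
    },
    "transmir": {
        "regulator": ("TF", "tf", "TF name"),
        "target": ("miRNA", "mirna", "miRNA name"),
        "score": ("Evidence", "evidence", "score"),
    },
    "htftarget": {
        "regulator": ("TF", "tf"),
        "target": ("target", "Target", "gene", "Gene"),
        "score": ("evidence", "Evidence", "tissue", "score"),
    },
    "string": {
        "regulator": ("node1", "protein1"),
        "target": ("node2", "protein2"),
        "score": ("combined_score", "score"),
    },
}


def read_prediction_table(path: str | Path, source: str) -> pd.DataFrame:
    """Read a regulator->target prediction table for a known source dialect."""
    if source not in _PREDICTION_DIALECTS:
        raise ConfigurationError(
            f"unknown prediction source {source!r}; expected one of {sorted(_PREDICTION_DIALECTS)}"
        )
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    dialect = _PREDICTION_DIALECTS[source]

    def find(role: str, required: bool) -> str | None:
        for cand in dialect[role]:
            if cand in df.columns:
                return cand
        if required:
            raise FormatError(f"{path}: no {role} column among {dialect[role]}")
        return None

    if df.shape[0] == 0:
        log.warning("%s: empty prediction table (%s)", path, source)
        return interaction_table([], source)
    reg = find("regulator", required=True)
    tgt = find("target", required=True)
    sc = find("score", required=False)
    out = pd.DataFrame(
        {
            "regulator_id": df[reg].astype(str).str.strip(),
            "target_id": df[tgt].astype(str).str.strip(),
            "score": pd.to_numeric(df[sc], errors="coerce") if sc else np.nan,
        }
    )
    return interaction_table(out, source)


_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_geo_series_matrix(
    path: str | Path,
    probe_map: Mapping[str, str] | pd.Series,
    characteristic_patterns: Mapping[str, str] | None = None,
    log_transform: bool = False,
) -> tuple[ExpressionMatrix, CohortAnnotation]:
    """Read a GEO series-matrix file.

    Probes are mapped to symbols via ``probe_map`` (unmapped probes are
    dropped with a logged count; multi-probe symbols collapse to the
    highest-mean probe). ``characteristic_patterns`` maps annotation fields
    to key substrings searched in the ``!Sample_characteristics_ch1`` lines,
    e.g. ``{"grade": "grade"}`` matches ``"grade: high"``.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing file: {path}")
    meta: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.lower().startswith(_TABLE_BEGIN):
                in_table, saw_begin = True, True
                continue
            if line.lower().startswith(_TABLE_END):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                meta.append(next(csv.reader([line], delimiter="\t")))
    if not (saw_begin and saw_end):
        raise FormatError(f"{path}: missing series-matrix table markers")
    if not table_lines:
        raise FormatError(f"{path}: empty probe table")

    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    df.columns = [str(c).strip('"') for c in df.columns]
    df.index = [str(ix).strip('"') for ix in df.index]
    df = df.apply(pd.to_numeric, errors="coerce")

    pmap = dict(probe_map) if not isinstance(probe_map, pd.Series) else probe_map.to_dict()
    mapped = [pmap.get(p) for p in df.index]
    n_unmapped = sum(1 for m in mapped if m is None)
    if n_unmapped:
        log.info("%s: dropped %d unmapped probes", path, n_unmapped)
    keep = [m is not None for m in mapped]
    df = df.loc[keep]
    if df.shape[0] == 0:
        raise FormatError(f"{path}: all probes unmapped")
    df.index = pd.Index([m for m in mapped if m is not None], name="symbol")
    df = collapse_duplicate_features(df)
    if log_transform:
        df = np.log2(df + 1.0)
    matrix = ExpressionMatrix(data=df, transformed=log_transform)

    # sample characteristics -> annotation
    samples = list(df.columns)
    ann = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    for col in ANNOTATION_COLUMNS:
        ann[col] = np.nan
    ann["tissue"] = "tumor"
    ann["endpoint"] = "overall"
    for col in ("stage", "grade", "invasiveness"):
        ann[col] = "unknown"
    patterns = characteristic_patterns or {}
    char_rows = [m for m in meta if m and m[0].startswith("!Sample_characteristics")]
    for row in char_rows:
        values = [v.strip('"') for v in row[1:]]
        for field_name, key in patterns.items():
            rx = re.compile(rf"^\s*{re.escape(key)}\s*[:=]\s*(.+)$", re.IGNORECASE)
            for sample, value in zip(samples, values):
                m = rx.match(value)
                if m:
                    parsed: object = m.group(1).strip()
                    if field_name in ("survival_time", "survival_event", "progression"):
                        parsed = pd.to_numeric(parsed, errors="coerce")
                    ann.loc[sample, field_name] = parsed
    for col in ("survival_time", "survival_event", "progression"):
        ann[col] = pd.to_numeric(ann[col], errors="coerce")
    return matrix, CohortAnnotation(table=ann)


def read_annotation(path: str | Path) -> CohortAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("survival_time", "survival_event", "progression"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return CohortAnnotation(table=df)


def write_annotation(annotation: CohortAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="sample_id")
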