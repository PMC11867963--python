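"""End-to-end discovery pipeline with a reproducible run manifest.

``run_discovery`` executes the eight stages in order — cohort
(simulate or load), aggressiveness tertiles, four-criteria screen,
network + random-walk hub ranking, hub-signature scoring, survival
stratification, GSEA panels, and the miRNA association screen — writing
every table as tab-separated text and recording a content digest for each
output in the manifest. A single global seed fans out to per-stage
substreams, so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .association_screen import rank_negative_regulators, signature_correlation
from .differential_screen import run_screen, venn_counts
from .enrichment import gsea
from .errors import ConfigurationError, DataError, OncoscreenError
from .network_hub import build_network, random_walk_scores, rank_hub_genes
from .signature_scoring import (
    median_split,
    scores_as_series,
    signature_score,
    tertile_groups,
    zscore_matrix,
)
from .survival_analysis import best_cutoff_split, best_cutoff_table, survival_flag
from .synthetic_cohort import SyntheticCohort, SyntheticConfig, generate_cohort, write_cohort
from .types import CohortAnnotation, ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "StageRecord", "PipelineStageError", "run_discovery"]


@dataclass(frozen=True)
class PipelineConfig:
    outdir: Path
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    inputs: Mapping[str, str] | None = None  # expression/annotation/mirna/network/gene_sets
    q_cut: float = 0.05
    surv_p_cut: float = 0.05
    cutoff_pct_range: tuple[float, float] = (10.0, 90.0)
    cutoff_min_group: int = 10
    gsea_n_perm: int = 1000
    gsea_perm_type: str = "auto"  # phenotype when both classes >= 7, else gene_set
    rwr_restart: float = 0.5
    rwr_tol: float = 1e-10
    hub_signature_size: int = 8
    top_k_mirnas: int = 2
    emt_set_name: str = "EMT_SURROGATE"

    def __post_init__(self) -> None:
        if self.synthetic is None and self.inputs is None:
            raise ConfigurationError("config needs either a synthetic block or input paths")
        for name, lo, hi in (("q_cut", 0, 1), ("surv_p_cut", 0, 1)):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ConfigurationError(f"{name} must lie in ({lo}, {hi}], got {v}")
        if not (0 < self.rwr_restart <= 1):
            raise ConfigurationError("rwr_restart must lie in (0, 1]")
        if self.gsea_perm_type not in ("auto", "phenotype", "gene_set"):
            raise ConfigurationError(f"unknown gsea_perm_type {self.gsea_perm_type!r}")
        object.__setattr__(self, "outdir", Path(self.outdir))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        synth = raw.pop("synthetic", None)
        if synth is not None:
            synth = SyntheticConfig.from_mapping(synth)
        if "cutoff_pct_range" in raw:
            raw["cutoff_pct_range"] = tuple(raw["cutoff_pct_range"])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(synthetic=synth, **raw)


@dataclass
class StageRecord:
    name: str
    outputs: dict[str, str]  # filename -> sha256 digest
    seconds: float


@dataclass
class RunManifest:
    stages: list[StageRecord] = field(default_factory=list)
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    wall_time: float = 0.0

    @property
    def stage_names(self) -> list[str]:
        return [s.name for s in self.stages]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "wall_time": self.wall_time,
            "parameters": self.parameters,
            "stages": [asdict(s) for s in self.stages],
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


class PipelineStageError(OncoscreenError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: RunManifest, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


class _Run:
    """Mutable state threaded through the stages."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.manifest = RunManifest(
            parameters={k: v for k, v in asdict(config).items() if k != "inputs"},
            seed=config.seed,
        )
        ss = np.random.SeedSequence(config.seed).spawn(2)
        self.synthetic_seed = int(ss[0].generate_state(1)[0] % (2**31))
        self.gsea_seed = int(ss[1].generate_state(1)[0] % (2**31))
        self.cohort: SyntheticCohort | None = None
        self.expression: ExpressionMatrix | None = None
        self.mirna: ExpressionMatrix | None = None
        self.annotation: CohortAnnotation | None = None
        self.gene_sets: list[GeneSet] = []
        self.network = None
        self.targets: list[str] = []
        self.hub_set: GeneSet | None = None
        self.hub_scores = None
        self.aggressiveness = None
        self.emt_scores = None


def run_discovery(config: PipelineConfig) -> RunManifest:
    """Execute all stages; any failure aborts with the stage name and a
    partial manifest attached to the raised :class:`PipelineStageError`."""
    t0 = time.monotonic()
    run = _Run(config)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    stages = (
        ("cohort", _stage_cohort),
        ("aggressiveness", _stage_aggressiveness),
        ("screen", _stage_screen),
        ("network", _stage_network),
        ("signature", _stage_signature),
        ("stratification", _stage_stratification),
        ("gsea", _stage_gsea),
        ("association", _stage_association),
    )
    for name, fn in stages:
        start = time.monotonic()
        try:
            outputs = fn(run)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            run.manifest.wall_time = time.monotonic() - t0
            run.manifest.to_json(outdir / "manifest.json")
            raise PipelineStageError(name, run.manifest, exc) from exc
        record = StageRecord(
            name=name,
            outputs={p.name: _digest(p) for p in outputs},
            seconds=time.monotonic() - start,
        )
        run.manifest.stages.append(record)
        log.info("stage %s complete (%.2fs, %d outputs)", name, record.seconds, len(outputs))
    run.manifest.wall_time = time.monotonic() - t0
    run.manifest.to_json(outdir / "manifest.json")
    return run.manifest


def _stage_cohort(run: _Run) -> list[Path]:
    cfg = run.config
    outdir = cfg.outdir
    if cfg.synthetic is not None:
        synth = SyntheticConfig.from_mapping(
            {**asdict(cfg.synthetic), "seed": run.synthetic_seed}
        )
        cohort = generate_cohort(synth)
        run.cohort = cohort
        run.expression = cohort.expression
        run.mirna = cohort.mirna_expression
        run.annotation = cohort.annotation
        run.gene_sets = [cohort.emt_set]
        run.network = cohort.network
        paths = write_cohort(cohort, outdir / "cohort")
        return list(paths.values())
    inputs = dict(cfg.inputs)
    run.expression = io_formats.read_firehose_matrix(inputs["expression"])
    run.annotation = io_formats.read_annotation(inputs["annotation"])
    if "mirna" in inputs:
        run.mirna = io_formats.read_firehose_matrix(inputs["mirna"])
    if "network" in inputs:
        run.network = io_formats.read_edge_list(inputs["network"])
    if "gene_sets" in inputs:
        run.gene_sets = io_formats.read_gmt(inputs["gene_sets"])
    return []


def _emt_set(run: _Run) -> GeneSet:
    for gs in run.gene_sets:
        if gs.name == run.config.emt_set_name:
            return gs
    raise DataError(f"aggressiveness gene set {run.config.emt_set_name!r} not found")


def _stage_aggressiveness(run: _Run) -> list[Path]:
    tumors = run.annotation.tumors
    z = zscore_matrix(run.expression, tumors)
    scores = signature_score(z, _emt_set(run))
    run.emt_scores = scores
    run.aggressiveness = tertile_groups(scores)
    out1 = _write(
        scores_as_series(scores).to_frame("aggressiveness_score"),
        run.config.outdir / "aggressiveness_scores.tsv",
    )
    out2 = _write(
        run.aggressiveness.to_frame("group"), run.config.outdir / "aggressiveness_groups.tsv"
    )
    return [out1, out2]


def _stage_screen(run: _Run) -> list[Path]:
    cfg = run.config
    surv = best_cutoff_table(
        run.expression,
        run.annotation,
        pct_range=cfg.cutoff_pct_range,
        min_group=cfg.cutoff_min_group,
        p_cut=cfg.surv_p_cut,
    )
    screen = run_screen(
        run.expression,
        run.annotation,
        run.aggressiveness,
        survival_flags=surv["flag"],
        q_cut=cfg.q_cut,
    )
    run.targets = list(screen.index[screen["oncogenic_target"]])
    venn = venn_counts(screen)
    return [
        _write(surv, cfg.outdir / "survival_screen.tsv"),
        _write(screen, cfg.outdir / "screen.tsv"),
        _write(venn.set_index(pd.RangeIndex(len(venn), name="row")), cfg.outdir / "venn_counts.tsv"),
    ]


def _stage_network(run: _Run) -> list[Path]:
    cfg = run.config
    if run.network is None:
        raise DataError("no interaction network available")
    if len(run.targets) < 2:
        raise DataError(f"too few oncogenic targets ({len(run.targets)}) to build a network")
    graph = build_network(run.network, restrict_to=run.targets)
    result = random_walk_scores(graph, restart=cfg.rwr_restart, tol=cfg.rwr_tol)
    ranked = rank_hub_genes(result)
    run.hub_scores = result
    hub_members = tuple(ranked[: cfg.hub_signature_size])
    run.hub_set = GeneSet(
        name="HUB_SIGNATURE", description="top random-walk hub genes", members=hub_members
    )
    table = result.scores.loc[ranked].to_frame()
    table["is_hub_signature"] = [g in set(hub_members) for g in table.index]
    return [_write(table, cfg.outdir / "hub_scores.tsv")]


def _stage_signature(run: _Run) -> list[Path]:
    tumors = run.annotation.tumors
    z = zscore_matrix(run.expression, tumors)
    scores = signature_score(z, run.hub_set)
    run.hub_signature_scores = scores
    return [
        _write(
            scores_as_series(scores).to_frame("hub_signature_score"),
            run.config.outdir / "hub_signature_scores.tsv",
        )
    ]


def _stage_stratification(run: _Run) -> list[Path]:
    cfg = run.config
    scores = scores_as_series(run.hub_signature_scores)
    split = median_split(run.hub_signature_scores)
    run.hub_split = split
    surv = run.annotation.survival_subset(run.annotation.tumors)
    aligned = scores.loc[[s for s in surv.index if s in scores.index]]
    surv = surv.loc[aligned.index]
    cut = best_cutoff_split(
        aligned.to_numpy(),
        surv["survival_time"].to_numpy(),
        surv["survival_event"].to_numpy(),
        pct_range=cfg.cutoff_pct_range,
        min_group=cfg.cutoff_min_group,
    )
    rows = pd.DataFrame(
        {
            "method": ["median_split", "best_cutoff"],
            "threshold": [float(aligned.median()), cut.threshold],
            "p_value": [np.nan, cut.logrank.p_value],
            "chi_square": [np.nan, cut.logrank.chi_square],
            "flag": [np.nan, survival_flag(cut, cfg.surv_p_cut)],
            "n_thresholds": [1, cut.n_thresholds_scanned],
        }
    ).set_index("method")
    # median-split log-rank for comparison
    from .survival_analysis import logrank_test

    hi = split.loc[aligned.index] == "high"
    lr = logrank_test(
        (surv.loc[~hi, "survival_time"], surv.loc[~hi, "survival_event"]),
        (surv.loc[hi, "survival_time"], surv.loc[hi, "survival_event"]),
    )
    rows.loc["median_split", ["p_value", "chi_square"]] = [lr.p_value, lr.chi_square]
    rows.loc["median_split", "flag"] = (
        "poor_survival" if lr.p_value < cfg.surv_p_cut and lr.direction > 0
        else ("good_survival" if lr.p_value < cfg.surv_p_cut and lr.direction < 0 else "none")
    )
    return [_write(rows, cfg.outdir / "survival_stratification.tsv")]


def _stage_gsea(run: _Run) -> list[Path]:
    cfg = run.config
    tumors = run.annotation.tumors
    expr = run.expression.subset_samples(tumors)
    phenotype = run.hub_split
    class_sizes = phenotype.value_counts()
    if cfg.gsea_perm_type == "auto":
        perm_type = "phenotype" if class_sizes.min() >= 7 else "gene_set"
    else:
        perm_type = cfg.gsea_perm_type
    panels = [gs for gs in run.gene_sets] + [run.hub_set]
    results = gsea(
        expr,
        phenotype,
        panels,
        n_perm=cfg.gsea_n_perm,
        perm_type=perm_type,
        seed=run.gsea_seed,
    )
    table = pd.DataFrame(
        [
            {
                "gene_set": r.gene_set,
                "es": r.es,
                "nes": r.nes,
                "nominal_p": r.nominal_p,
                "fdr_q": r.fdr_q,
                "n_permutations": r.n_permutations,
                "leading_edge_size": len(r.leading_edge),
            }
            for r in results
        ]
    ).set_index("gene_set")
    return [_write(table, cfg.outdir / "gsea.tsv")]


def _stage_association(run: _Run) -> list[Path]:
    cfg = run.config
    outputs = []
    if run.mirna is None:
        raise DataError("no miRNA matrix available for the association stage")
    tumors = run.annotation.tumors
    ranking = rank_negative_regulators(
        run.mirna.subset_samples(tumors),
        run.expression.subset_samples(tumors),
        run.hub_set,
        top_k=cfg.top_k_mirnas,
    )
    outputs.append(_write(ranking.table, cfg.outdir / "mirna_ranking.tsv"))

    # suppressor-miRNA signature score vs hub signature score
    mir_set = GeneSet(
        name="SUPPRESSOR_MIRNA_GS",
        description="top anti-correlated miRNAs",
        members=ranking.top,
    )
    z_mir = zscore_matrix(run.mirna, tumors)
    mir_scores = signature_score(z_mir, mir_set)
    corr = signature_correlation(
        run.hub_signature_scores, mir_scores, "HUB_SIGNATURE", mir_set.name
    )
    corr_df = pd.DataFrame(
        [{"a": corr.id_a, "b": corr.id_b, "r": corr.r, "p_value": corr.p_value, "n": corr.n}]
    ).set_index("a")
    outputs.append(_write(corr_df, cfg.outdir / "signature_correlations.tsv"))

    # final report: the hub signature named with its planted overlap if known
    report = {
        "n_oncogenic_targets": len(run.targets),
        "hub_signature": ",".join(run.hub_set.members),
        "top_mirnas": ",".join(ranking.top),
        "hub_vs_mirna_r": corr.r,
    }
    if run.cohort is not None:
        planted = set(run.cohort.truth.planted_gene_ids)
        report["hub_signature_planted_fraction"] = (
            sum(g in planted for g in run.hub_set.members) / len(run.hub_set)
        )
    path = cfg.outdir / "report.json"
    path.write_text(json.dumps(report, indent=2) + "\n")
    outputs.append(path)
    return outputs
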