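"""Synthetic tumor/normal cohorts with planted, recoverable structure.

The generator emulates the statistical regimes the discovery pipeline
assumes so that every stage has a ground-truth recovery test:

* background gene expression is Gaussian on a log scale with gene-specific
  baselines (the pipeline consumes normalized matrices, not raw counts);
* a planted gene module is shifted upward in tumors by a configured
  standardized effect and rises with a latent U(0,1) "aggressiveness"
  variable (tumor noise is shrunk so the configured effect size is also
  the realized standardized tumor-vs-normal difference);
* an EMT-surrogate gene set tracks the latent variable (with the latent
  term centered so these genes carry no tumor-vs-normal shift and stay out
  of the four-criteria intersection), giving the aggressiveness classifier
  something to recover;
* planted suppressor miRNAs are constructed to a target negative Pearson
  correlation with the planted-module mean profile;
* tumor stage/grade/invasiveness derive from the latent variable with a
  configurable misclassification rate;
* survival is exponential with log-hazard proportional to the planted
  signature z-score sum, with a configured fraction of subjects censored
  uniformly within their event time;
* the interaction network is an Erdos-Renyi background plus a dense
  planted-gene clique sampled at ``hub_edge_prob``.

Identical config + seed yields byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import ANNOTATION_COLUMNS, CohortAnnotation, ExpressionMatrix, GeneSet

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticCohort", "generate_cohort",
           "cohort_truth_report", "write_cohort"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_normal: int = 50
    n_tumor: int = 400
    n_genes: int = 2000
    n_mirnas: int = 200
    n_planted_genes: int = 27
    effect_size_d: float = 1.5
    aggressiveness_slope: float = 1.5
    n_planted_mirnas: int = 2
    mirna_anticorr_rho: float = -0.5
    hazard_beta: float = 0.4
    baseline_hazard: float = 0.001  # events per day
    censor_rate: float = 0.3
    stage_noise: float = 0.1
    network_background_edge_prob: float = 0.002
    hub_edge_prob: float = 0.8
    emt_set_size: int = 100
    emt_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("censor_rate", "stage_noise", "network_background_edge_prob", "hub_edge_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_normal", "n_tumor", "n_genes", "n_mirnas"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_planted_genes > self.n_genes:
            raise ConfigurationError("n_planted_genes exceeds n_genes")
        if self.n_planted_genes + self.emt_set_size > self.n_genes:
            raise ConfigurationError("planted + EMT-surrogate genes exceed n_genes")
        if self.n_planted_mirnas > self.n_mirnas:
            raise ConfigurationError("n_planted_mirnas exceeds n_mirnas")
        if not (-1.0 < self.mirna_anticorr_rho <= 0.0):
            raise ConfigurationError("mirna_anticorr_rho must lie in (-1, 0]")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")

    @classmethod
    def null(cls, **overrides) -> "SyntheticConfig":
        """All planted effects switched off (calibration runs)."""
        base = dict(
            effect_size_d=0.0,
            aggressiveness_slope=0.0,
            mirna_anticorr_rho=0.0,
            hazard_beta=0.0,
            emt_slope=0.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SyntheticConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown synthetic config keys: {sorted(unknown)}")
        return cls(**dict(mapping))


@dataclass(frozen=True)
class SyntheticTruth:
    planted_gene_ids: tuple[str, ...]
    planted_mirna_ids: tuple[str, ...]
    emt_gene_ids: tuple[str, ...]
    latent_aggressiveness: pd.Series  # indexed by tumor sample id
    planted_signature_score: pd.Series  # z-score sum driving the hazard


@dataclass(frozen=True)
class SyntheticCohort:
    expression: ExpressionMatrix
    mirna_expression: ExpressionMatrix
    annotation: CohortAnnotation
    emt_set: GeneSet
    network: nx.Graph
    truth: SyntheticTruth
    config: SyntheticConfig = field(repr=False, default=None)


def _shrunk_sd(slope: float) -> float:
    """Tumor noise SD such that slope*latent + noise has unit variance."""
    return float(np.sqrt(max(1.0 - slope**2 / 12.0, 0.05)))


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_expr, rng_mirna, rng_surv, rng_net, rng_ann = (np.random.default_rng(s) for s in streams)

    normal_ids = [f"TCGA-SN-{i:04d}-11A" for i in range(cfg.n_normal)]
    tumor_ids = [f"TCGA-ST-{i:04d}-01A" for i in range(cfg.n_tumor)]
    samples = normal_ids + tumor_ids
    gene_ids = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    mirna_ids = np.array([f"hsa-mir-s{i:04d}" for i in range(cfg.n_mirnas)])

    picked = rng_expr.choice(cfg.n_genes, size=cfg.n_planted_genes + cfg.emt_set_size, replace=False)
    planted_idx = picked[: cfg.n_planted_genes]
    emt_idx = picked[cfg.n_planted_genes :]

    latent = rng_expr.uniform(0.0, 1.0, size=cfg.n_tumor)

    mu_g = rng_expr.uniform(2.0, 12.0, size=cfg.n_genes)
    x = mu_g[:, None] + rng_expr.normal(size=(cfg.n_genes, len(samples)))

    tum = slice(cfg.n_normal, None)
    centered = latent - 0.5
    if cfg.n_planted_genes:
        sd = _shrunk_sd(cfg.aggressiveness_slope)
        x[planted_idx, tum] = (
            mu_g[planted_idx, None]
            + cfg.effect_size_d
            + cfg.aggressiveness_slope * centered[None, :]
            + sd * rng_expr.normal(size=(cfg.n_planted_genes, cfg.n_tumor))
        )
    if cfg.emt_set_size:
        sd = _shrunk_sd(cfg.emt_slope)
        x[emt_idx, tum] = (
            mu_g[emt_idx, None]
            + cfg.emt_slope * centered[None, :]
            + sd * rng_expr.normal(size=(cfg.emt_set_size, cfg.n_tumor))
        )

    expr = ExpressionMatrix(
        data=pd.DataFrame(x, index=pd.Index(gene_ids, name="symbol"), columns=samples),
        transformed=True,
    )

    # planted signature z-score sum over tumors drives the hazard
    if cfg.n_planted_genes:
        sub = x[planted_idx, :][:, cfg.n_normal :]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
        score = z.sum(axis=0)
    else:
        score = np.zeros(cfg.n_tumor)
    score_s = pd.Series(score, index=tumor_ids, name="planted_signature_score")

    hazard = cfg.baseline_hazard * np.exp(cfg.hazard_beta * score)
    event_time = rng_surv.exponential(1.0 / hazard)
    censored = rng_surv.random(cfg.n_tumor) < cfg.censor_rate
    obs_time = np.where(censored, event_time * rng_surv.uniform(size=cfg.n_tumor), event_time)
    event = (~censored).astype(float)

    # miRNAs: background plus suppressors anti-correlated with the planted module
    mu_m = rng_mirna.uniform(2.0, 10.0, size=cfg.n_mirnas)
    m = mu_m[:, None] + rng_mirna.normal(size=(cfg.n_mirnas, len(samples)))
    planted_mirna_idx = (
        rng_mirna.choice(cfg.n_mirnas, size=cfg.n_planted_mirnas, replace=False)
        if cfg.n_planted_mirnas
        else np.array([], dtype=int)
    )
    if cfg.n_planted_mirnas and cfg.n_planted_genes:
        profile = x[planted_idx, :].mean(axis=0)
        profile = (profile - profile.mean()) / profile.std(ddof=1)
        rho = cfg.mirna_anticorr_rho
        noise = rng_mirna.normal(size=(cfg.n_planted_mirnas, len(samples)))
        m[planted_mirna_idx, :] = (
            mu_m[planted_mirna_idx, None]
            + rho * profile[None, :]
            + np.sqrt(1.0 - rho**2) * noise
        )
    mirna = ExpressionMatrix(
        data=pd.DataFrame(m, index=pd.Index(mirna_ids, name="symbol"), columns=samples),
        transformed=True,
    )

    # clinical annotation
    flip = lambda truth_vec: truth_vec ^ (rng_ann.random(cfg.n_tumor) < cfg.stage_noise)
    advanced = flip(latent > np.median(latent))
    high_grade = flip(latent > 0.5)
    invasive = flip(latent > 0.6)
    progression = np.minimum((latent * 4).astype(int) + 1, 4)

    ann = pd.DataFrame(index=pd.Index(samples, name="sample_id"), columns=list(ANNOTATION_COLUMNS))
    ann["tissue"] = ["normal"] * cfg.n_normal + ["tumor"] * cfg.n_tumor
    ann["endpoint"] = "overall"
    ann.loc[normal_ids, ["stage", "grade", "invasiveness"]] = "unknown"
    ann.loc[tumor_ids, "stage"] = np.where(advanced, "advanced", "early")
    ann.loc[tumor_ids, "grade"] = np.where(high_grade, "high", "low")
    ann.loc[tumor_ids, "invasiveness"] = np.where(invasive, "muscle_invasive", "non_muscle_invasive")
    ann.loc[tumor_ids, "progression"] = progression
    ann.loc[tumor_ids, "survival_time"] = obs_time
    ann.loc[tumor_ids, "survival_event"] = event
    for col in ("survival_time", "survival_event", "progression"):
        ann[col] = pd.to_numeric(ann[col], errors="coerce")
    annotation = CohortAnnotation(table=ann)

    # interaction network: ER background + planted clique
    net_seed = int(streams[3].generate_state(1)[0] % (2**31))
    graph = nx.relabel_nodes(
        nx.fast_gnp_random_graph(cfg.n_genes, cfg.network_background_edge_prob, seed=net_seed),
        dict(enumerate(gene_ids)),
    )
    planted_genes = gene_ids[planted_idx]
    for i in range(len(planted_genes)):
        for j in range(i + 1, len(planted_genes)):
            if rng_net.random() < cfg.hub_edge_prob:
                graph.add_edge(planted_genes[i], planted_genes[j])
    for _, _, data in graph.edges(data=True):
        data["weight"] = float(rng_net.uniform(0.4, 1.0))

    emt_set = GeneSet(
        name="EMT_SURROGATE",
        description="latent-aggressiveness-correlated surrogate signature",
        members=tuple(gene_ids[emt_idx]),
    )
    truth = SyntheticTruth(
        planted_gene_ids=tuple(planted_genes),
        planted_mirna_ids=tuple(mirna_ids[planted_mirna_idx]),
        emt_gene_ids=tuple(gene_ids[emt_idx]),
        latent_aggressiveness=pd.Series(latent, index=tumor_ids, name="latent"),
        planted_signature_score=score_s,
    )
    return SyntheticCohort(
        expression=expr,
        mirna_expression=mirna,
        annotation=annotation,
        emt_set=emt_set,
        network=graph,
        truth=truth,
        config=cfg,
    )


def cohort_truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Realized effect sizes / correlations / hazard ratio of the planted
    features, computed from the generated data (not echoed from config)."""
    from .survival_analysis import logrank_test

    expr = cohort.expression.data
    normals = cohort.annotation.normals
    tumors = cohort.annotation.tumors

    # realized hazard ratio from a median split of the planted signature
    # score (Pike estimator (O1/E1)/(O2/E2) from the log-rank table)
    surv = cohort.annotation.survival_subset(tumors)
    score = cohort.truth.planted_signature_score.loc[surv.index]
    hi = score > score.median()
    lr = logrank_test(
        (surv.loc[~hi, "survival_time"], surv.loc[~hi, "survival_event"]),
        (surv.loc[hi, "survival_time"], surv.loc[hi, "survival_event"]),
    )
    (o1, o2), (e1, e2) = lr.observed_events, lr.expected_events
    hr = (o2 / e2) / (o1 / e1) if min(e1, e2) > 0 and o1 > 0 else float("nan")

    if cohort.truth.planted_gene_ids:
        profile = expr.loc[list(cohort.truth.planted_gene_ids)].mean(axis=0)
    else:
        profile = pd.Series(0.0, index=expr.columns)

    rows = []
    for gid in cohort.truth.planted_gene_ids:
        t_vals = expr.loc[gid, tumors].to_numpy(dtype=float)
        n_vals = expr.loc[gid, normals].to_numpy(dtype=float)
        pooled_sd = np.sqrt(
            (
                (t_vals.size - 1) * t_vals.var(ddof=1)
                + (n_vals.size - 1) * n_vals.var(ddof=1)
            )
            / (t_vals.size + n_vals.size - 2)
        )
        d = (t_vals.mean() - n_vals.mean()) / pooled_sd if pooled_sd > 0 else float("nan")
        rows.append((gid, "gene", float(d), float("nan"), float(hr)))
    for mid in cohort.truth.planted_mirna_ids:
        mvals = cohort.mirna_expression.data.loc[mid]
        r = float(np.corrcoef(mvals.to_numpy(dtype=float), profile.to_numpy(dtype=float))[0, 1])
        rows.append((mid, "mirna", float("nan"), r, float(hr)))
    return pd.DataFrame(
        rows, columns=["feature_id", "kind", "realized_d", "realized_r", "realized_hr"]
    ).set_index("feature_id")


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort in the pipeline's own file dialects so the readers
    are exercised end-to-end."""
    from . import io_formats

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "mirna": outdir / "mirna.tsv",
        "annotation": outdir / "annotation.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "network": outdir / "network.tsv",
        "truth": outdir / "truth.tsv",
    }
    io_formats.write_firehose_matrix(cohort.expression, paths["expression"])
    io_formats.write_firehose_matrix(cohort.mirna_expression, paths["mirna"])
    io_formats.write_annotation(cohort.annotation, paths["annotation"])
    planted = GeneSet(
        name="PLANTED", description="ground-truth planted module",
        members=cohort.truth.planted_gene_ids,
    ) if cohort.truth.planted_gene_ids else None
    sets = [cohort.emt_set] + ([planted] if planted else [])
    io_formats.write_gmt(sets, paths["gene_sets"])
    io_formats.write_edge_list(cohort.network, paths["network"])
    cohort_truth_report(cohort).to_csv(paths["truth"], sep="\t")
    return paths
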