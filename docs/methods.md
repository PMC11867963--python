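# Methods

`oncoscreen` reimplements a multi-stage discovery workflow used in bulk
tumor transcriptomics: starting from an expression matrix with clinical
annotation, it stratifies patients by a signature-derived aggressiveness
score, screens every gene against four joint criteria, prioritizes the
surviving candidates by network diffusion, and closes the loop with
enrichment and regulator (miRNA / transcription-factor) association
screens. This note records the models, the defaults, and the design
decisions taken where the procedure was genuinely open.

## Signature scores and patient stratification

A signature score for patient *j* and gene set *S* is the plain z-sum

    score_j = sum_{g in S} z_gj,     z_gj = (x_gj - mean_g) / sd_g,

with per-gene mean and sample SD (n−1 denominator) computed **over the
sample subset entering the comparison** — tumors only for the
aggressiveness score — so that normal samples do not dominate the
standardization. Zero-variance genes emit z = 0 and are flagged rather
than dropped, keeping matrix shapes stable. No rank-based (ssGSEA/GSVA)
scoring is offered; the score is deliberately the plain z-sum.

Stratification is either by tertiles (low / intermediate / high; remainder
samples assigned low-first, so n = 10 splits 4/3/3) or by an equal median
split (odd n puts the extra sample in "low"). Ties in score are broken by
sample identifier, making both splits deterministic and
permutation-invariant.

## The four-criteria screen

A gene is an oncogenic-target candidate iff it is simultaneously

1. upregulated in tumor vs normal tissue — pooled-variance Student's t,
   BH-adjusted q < 0.05 and positive direction;
2. successively upregulated across aggressiveness tertiles — one-way
   ANOVA q < 0.05 **and** strictly increasing tertile means (a literal
   reading of "successive");
3. upregulated in advanced- (III/IV) vs early-stage (I/II) tumors —
   t-test, q < 0.05, positive direction;
4. associated with poor survival at its best expression cutoff (below),
   at nominal log-rank p < 0.05.

BH adjustment is applied within each expression comparison separately
(three independent FDR families), the standard practice when the three
contrasts answer different questions. The survival criterion uses nominal
p because the dichotomization scan has no exchangeable family to adjust
within; see the caveat below. Welch's t is available behind a flag but the
default is the pooled-variance test. Degenerate inputs are defined
exactly: zero pooled variance with equal means gives t = 0, p = 1; with
unequal means p = 0 flagged `degenerate`.

## Survival analysis and the best-cutoff scan

Kaplan–Meier curves use the product-limit estimator; subjects censored at
an event time remain at risk at that time. The two-group comparison is
the Mantel–Cox log-rank test (1-df chi-square), reporting per-group
observed and expected events and a direction (which group died more than
expected).

"Best cutoff" dichotomization scans every distinct expression value
between the 10th and 90th percentile as a threshold (low: value ≤ t,
high: value > t), requires at least 10 samples per arm, and returns the
threshold minimizing the log-rank p. Ties in p resolve toward the more
balanced split, then the smaller threshold. **The reported minimum p is
unadjusted for the scan** — the conventional optimal-cutpoint practice —
and is anti-conservative: under the null the per-gene flag rate at
p < 0.05 is several-fold the nominal level. The implementation logs a
multiplicity warning with the number of thresholds scanned, and the
null-calibration suite checks only the three FDR-gated expression
criteria against the 7% ceiling for exactly this reason. The scan range,
group floor, and tie rules are package choices; the original procedure's
candidate set is not recoverable.

Overall survival is the default endpoint; a cancer-specific endpoint is
carried through the annotation schema. No Cox model is fitted anywhere;
the realized hazard ratio reported for synthetic cohorts is the Pike
estimator (O₂/E₂)/(O₁/E₁) from the log-rank table.

## Network hub scoring (random walk with restart)

Candidates are restricted onto an interaction network (STRING-style edge
list; candidates without any interaction are kept as isolated nodes and
reported). Hubs are ranked by steady-state energy diffusion: every node
starts with one energy unit and iterates

    e ← (1 − r) · P · e + r · e₀,

with P the column-normalized weighted adjacency (STRING combined scores
as weights when present, else 1) and restart r = 0.5 by default. Columns
of isolated nodes act as the identity, so they retain their unit energy.
Because P is column-stochastic, total energy is conserved at the node
count (checked to 1e-9), and the iteration converges to the unique
solution of (I − (1−r)P)e = re₀ for any r in (0, 1]. Pure diffusion
(r = 0) is excluded: it oscillates on bipartite graphs and reduces to
weighted-degree centrality elsewhere, whereas restart keeps a meaningful
"retained energy" notion and always converges. r is exposed on the CLI;
the iterative fix point is verified against the direct linear solve in
the test suite. Stopping tolerance 1e-10 on the L1 change, cap 10,000
iterations (non-convergence is reported, not raised).

## GSEA

Genes are ranked by signal-to-noise, (μ_A − μ_B)/(σ_A + σ_B), with each
class SD floored at 0.2·|mean| (0.2 when the mean is zero). The
enrichment score walks the ranked list: hits add |metric|^p normalized by
the in-set total (weight p = 1 by default; p = 0 recovers the classical
KS statistic), misses subtract 1/(N − N_hits); ES is the signed maximum
deviation, with an exact magnitude tie between the positive and negative
extremum resolving to the positive one (a documented tie rule so the
statistic is deterministic). Nominal p is the fraction of same-sign
permutation ES at least as large in magnitude; NES divides ES by the mean
magnitude of same-sign permutation ES; FDR q follows the
permutation-ratio procedure on the NES scale, computed separately for
positive and negative scores and capped at 1. Permutations are either
size-matched random gene sets (default; robust at small class sizes) or
phenotype-label permutations with full re-ranking (used when both classes
have ≥ 7 samples). Sets are filtered to 5–500 members present in the
matrix. All runs are seeded.

Over-representation (the functional-annotation stand-in) is the
upper-tail hypergeometric test with an optional EASE variant (overlap
discounted by one gene); membership lists must be supplied as GMT files —
no annotation database ships with the package.

## Regulator association screens

Suppressor-miRNA candidates are ranked by the arithmetic mean of their
Pearson correlations against each signature gene, computed on shared
samples, most negative first (a rank-sum aggregate is available behind a
flag). miRNAs with zero variance or detected (value > 0) in under 20% of
samples are excluded to avoid spurious correlations from near-constant
rows. TF prediction tables are consumed as given (mirDIP / TransmiR /
hTFtarget dialects), with per-TF coverage of a signature and Venn-style
intersection of common regulators. CRISPR dependency (chronos) tables are
summarized as per-cell-line means over a signature (negative = essential).

## The synthetic cohort generator

The generator defines the study conditions for every recovery and
calibration test. Defaults: 50 normal / 400 tumor samples, 2000 genes
(recovery runs in the acceptance suite use 500 genes for desk-scale
runtime — stated here as the package's problem-size choice), 200 miRNAs,
27 planted genes, 2 planted miRNAs.

* **Expression** is Gaussian on a log scale with gene-specific baselines
  μ_g ~ U(2, 12) and unit noise — the pipeline consumes normalized
  matrices, so no count model is simulated.
* **Planted genes** are shifted by effect size d = 1.5 in tumors and rise
  with a latent U(0,1) aggressiveness variable at slope 1.5. The latent
  term is centered and the tumor noise SD shrunk to √(1 − slope²/12), so
  the configured d *is* the realized standardized tumor-vs-normal
  difference (verified by the truth report).
* **The EMT-surrogate set** (100 genes) tracks the latent variable with a
  centered slope of 1.0 and no tumor shift: it gives the aggressiveness
  classifier signal to recover without leaking into the four-criteria
  intersection, which keeps planted-gene precision a meaningful metric.
* **Stage / grade / invasiveness** derive from latent thresholds
  (median, 0.5, 0.6) with 10% misclassification; progression is the
  latent quartile. The latent variable is uniform, not tertile-discrete,
  so tertile classification is genuinely exercised downstream.
* **Survival** is exponential with hazard h₀·exp(β·score), h₀ = 0.001
  events/day, β = 0.4 per unit planted-signature z-sum. A censor_rate
  fraction (30%) of subjects is censored at a uniform fraction of their
  event time — this hits the configured censoring rate exactly; fully
  independent uniform censoring would require calibrating the censoring
  window against the heavy-tailed hazard distribution.
* **Planted miRNAs** are built as ρ·(standardized planted-module mean
  profile) + √(1−ρ²)·noise with ρ = −0.5, giving the configured Pearson
  anti-correlation in expectation.
* **The network** is an Erdős–Rényi background (edge probability 0.002)
  plus a planted-gene clique sampled at 0.8, with U(0.4, 1) edge weights.

Identical config + seed is byte-identical. Sample identifiers are
TCGA-style barcodes (sample-type codes 01/11), so barcode parsing and the
file writers/readers are exercised end-to-end.

**What the generator does not emulate:** real RNA-seq count noise,
batch and platform effects, correlated background co-expression,
non-exponential hazards, informative censoring, and the empirical
distributions or sample sizes of any public cohort. Recovery tests
therefore demonstrate that the pipeline recovers the structure it assumes
— not that the assumptions hold in real data.

## Numerical and degenerate-input conventions

* Duplicate feature rows collapse to the highest-mean row (idempotent;
  ties by file order). Firehose values are log2(x+1)-transformed by
  default before statistics (toggleable; the scale convention is not
  recoverable from upstream descriptions, and the transform makes the t /
  Pearson machinery defensible).
* Tumor/normal is derived from the barcode sample-type code (01–09 tumor,
  10–19 normal), the Firehose convention, rather than from clinical files.
* Missing values propagate and are pairwise-dropped in statistics; no
  imputation.
* Samples lacking survival time or event are excluded from survival
  analyses only.
* BH q-values come from the standard step-up; p-values outside [0,1] are
  rejected, not clamped.
* The pipeline seed fans out to per-stage substreams via spawned seed
  sequences, so a stage rerun reproduces its in-pipeline result.

## Known limitations

* The best-cutoff minimum p is anti-conservative by construction (see
  above); treat per-gene survival flags as a screening criterion, not an
  inference.
* The random-walk update rule, restart value, and tolerance are package
  choices; agreement with any particular published hub ranking can only
  be plausible, not exact.
* GSEA FDR by the permutation-ratio procedure is itself an estimate; at
  1000 permutations q-values below ~1e-3 saturate.
* The hypergeometric ORA inherits whatever bias the supplied universe
  carries; choose the universe to match the measured gene space.
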