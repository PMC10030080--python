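# Methods

This note documents the models, statistics and design choices behind
`scdebench`.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external runs.

## Model-based simulator (`sim_splat`)

### Generative model

For gene i, batch b and cell j:

1. Baseline means `m_i ~ Gamma(mean_shape, mean_rate)` (defaults 0.6, 0.3 —
   a strongly right-skewed distribution typical of expression means).
2. Batch factors `f_ib` drawn per (gene, batch) from
   `LogNormal(batch_facLoc, batch_facScale)`, folded above 1 and then
   inverted for a random half of the genes, so each batch shifts a random
   half of the genome up and the other half down.  Folding guarantees that
   `batch_facLoc` controls the *magnitude* of the shift.
3. DE factors: `round(de_prob * n_genes)` genes are chosen, half up and
   half down (`de_downProb` = 0.5).  A folded
   `LogNormal(de_facLoc, de_facScale)` magnitude g >= 1 multiplies the
   case-group mean of up genes; down genes get 1/g.  The *truth* records
   the direction and the applied factor (1 for null genes).
4. Library sizes `L_j ~ LogNormal(libsize_loc, libsize_scale)`.  Per-cell
   expected counts are the (batch, group) mean profile rescaled to sum to
   `L_j`, as in the splat model.
5. Counts are gamma-Poisson: `lambda ~ Gamma(1/phi, phi*mu)`,
   `y ~ Poisson(lambda)` — negative binomial with a single common
   dispersion `phi` (default 0.1).  The mean-dependent BCV trend of splat
   is not modeled; none of the package's experiments exercise it.
6. Dropout: each entry is zeroed independently with probability
   `1 / (1 + exp(-shape * (ln mu - mid)))`; with the conventional
   `shape = -1`, low-mean entries drop more often.  `mid` = 3.7 produces
   the sparse (>80% zeros) regime at desk scale; `mid` = 0.05 the mild
   one.  Both readings of the moderate dropout midpoint (0.05 / 0.5) are
   reachable through configuration; no value is hard-coded.

Reproducibility: one integer seed spawns independent substreams per stage
(means, DE selection, DE factors, batch factors, library sizes, counts,
dropout) and per batch, so identical parameters give bit-identical output
and appending a batch leaves earlier batches untouched.  Cells are ordered
batch-major with case cells before control cells; ids are `G%06d` /
`C%06d`.

### Presets and calibration

Presets were fixed by the packaged bisection routine
(`calibrate_libsize_loc`) at 1000 genes and two batches of 300/750 cells,
then frozen.  Depth is defined as the mean nonzero count after removing
genes with zero rate > 0.95.

| preset            | dropout mid | libsize_loc | realized depth | realized zero rate |
|-------------------|------------:|------------:|---------------:|-------------------:|
| sparse-80         | 3.7         | 8.0         | ~12            | ~0.87              |
| sparse80-depth77  | 3.7         | 10.55       | ~78            | ~0.61              |
| sparse80-depth10  | 3.7         | 7.85        | ~10.5          | ~0.87              |
| sparse80-depth4   | 3.7         | 7.1 (*)     | ~4.6           | ~0.93              |
| sparse40-depth77  | 0.05        | 11.1        | ~78            | ~0.12              |
| sparse40-depth4   | 0.05        | 7.4         | ~4             | ~0.59              |

(*) `sparse80-depth4` also flattens the gene-mean distribution
(`mean_shape` = 2): under the default skewed means, almost no gene
survives the 5%-expressed filter at depth 4 because the dropout
probability at the qualifying means sits exactly at the filter boundary.

Depth and sparsity trade off against each other in this model: without
splat's expression-outlier genes there is no mechanism to concentrate the
library in a few very deep genes, so the simultaneous combination
"depth 77 and >80% zeros" is not reachable (the frontier tops out near
76% zeros at depth 77, measured across library size, dispersion and
dropout variants).  The presets therefore pin one property each:
`sparse-80` is sparsity-first, the depth presets are depth-first, and the
realized value of the other property is listed above.  This is the main
respect in which the simulator's regimes are looser than real sparse
deep-sequenced data.

Other known gaps between the simulator and real data: genes are
independent (no correlation structure, no cell subtypes or trajectories),
dropout is independent across entries given the mean, and batch effects
are purely multiplicative per (gene, batch).  Tests passing on these data
show correctness of the pipeline and the expected *relative* behavior of
workflows (e.g. covariate modeling helping under confounded designs), not
performance guarantees on any particular real dataset.

## Model-free simulator (`sim_downsample`)

From any source count matrix: genes with zero rate > 0.95 are removed;
each batch's cells are split case/control at the configured ratio
(`round(ratio * n)` case cells, uniformly at random); two disjoint random
gene sets of `round(de_fraction/2 * n_genes)` genes each are chosen; one
set is thinned in the case group ("down"), the other in the control group
("up"); thinning replaces each count c by `Binomial(c, p)` with one
`p ~ Beta(2, 2)` per gene, applied identically in every batch (the
minimal reading; a per-batch redraw is available behind `p_per_batch`).
`Beta(2,2)` has median 0.5, so DE genes have a median fold change of 2.
Non-targeted entries are bit-identical to the input and zeros stay zero.

## Preprocessing (`preprocess`)

* Gene filter: keep genes with zero fraction <= 0.95 across analyzed
  cells; library sizes are recomputed on the retained genes (pre-filter
  totals available via argument).  Idempotent.
* Log-normalization: `log2(c_ij / L_j * 1e4 + 1)`.  Base 2 is the default
  so that its composition with the logFC estimator is self-consistent;
  natural log by argument.
* logFC: mean of log-normalized values over *nonzero* cells, case minus
  control.  Genes with no nonzero cell in a group are flagged
  (`case_all_zero` / `control_all_zero` / `both_zero`) and report
  non-finite logFC; flagged genes are excluded from error-ratio and
  distortion denominators.  An all-cell mean is available for sensitivity
  analysis.

## DE methods (`de_methods`)

* **Wilcoxon**: two-sided rank-sum per gene (tie-corrected normal
  approximation; exact enumeration at tiny tie-free sizes).  Sign from the
  logFC convention above; constant genes get p = 1, sign 0.
* **Covariate NB GLM**: per gene,
  `log E(y) = a0 + a1 log L + sum_b beta_b I_b + gamma I_case`,
  NB family with a per-gene dispersion estimated by moments from a Poisson
  fit, then a Wald z (or LRT) on gamma.  Library size may instead enter as
  a fixed offset.  The model requires a balanced design (every batch
  contains both groups) when batch covariates are included; an unbalanced
  batch raises an error naming it.  Failed fits (separation, singularity)
  are flagged with p = 1.  The group coefficient is reported on the log2
  scale to match the logFC convention.
* **Pseudobulk**: counts summed per batch x group unit (or per explicit
  sample label); two-sided t-test on `log2(CPM + 1)` of units, unpaired by
  default with a paired-by-batch option.  At least two units per group are
  required — no replication, no test.
* **Meta-analysis**: per batch, genes are re-filtered and log-normalized
  independently, a within-batch engine runs (Welch t on log-normalized
  values by default; Wilcoxon for p-only combination), and results are
  combined:
  * *weighted Fisher*: one-sided p-values are combined in both directions
    with weights proportional to batch cell counts (gamma
    reparameterization: p maps to an upper `Gamma(w_k, 2)` quantile, the
    sum is referred to `Gamma(sum w, 2)`; equal weights recover Fisher's
    chi-square).  The smaller directional p is doubled, capped at 1, and
    sets the sign.
  * *fixed effects*: inverse-variance pooling of per-batch effects with a
    Wald z on the pooled effect.
  * *random effects*: DerSimonian–Laird method-of-moments tau² added to
    the within-batch variances before pooling.
  A gene absent from a batch (filtered there) contributes no evidence from
  it; weights renormalize over the contributing batches.  Exact numeric
  agreement with any external meta-analysis implementation is not claimed.
* **BH correction**: literal step-up with enforced monotonicity; NaN
  p-values propagate and are excluded from the test count.
* **Signed scores**: `-log(p) * sign(logFC)`, base 10 by default (ranks —
  and hence Spearman similarities — are base-invariant); p = 0 clamps to
  1e-300.
* External engines (moderated-t, quasi-likelihood variants, hurdle and
  zero-inflation models, all BEC methods) are not reimplemented; their
  results enter via `read_external_result` on the common TSV schema.

## Evaluation (`metrics`)

Rank-based metrics share one ordering: p ascending, ties broken by larger
absolute signed score, then lexicographic gene id.

* **F_beta** (default beta = 0.5, precision weighted) is computed per
  direction on the q < 0.05 calls, counting a call correct only when the
  declared sign matches the simulated direction.  An optional
  `|logFC| > 0.5` post-filter mode reproduces the stricter selection
  experiment.
* **pAUPR**: `(1/T) * integral_0^T precision d(recall)` with T = 0.5;
  precision integrated as a right-continuous step function of recall, and
  a true positive again requires the matching sign.
* **Error ratio**: `100 * #(sign contradicts truth) / #DE genes`, over all
  simulated DE genes or only the detected ones (q < 0.05); genes with
  flagged non-finite logFC are excluded from both counts.
* **Distortion**: mean over DE genes of
  `1 - sign(lfc_raw) * <(1,1),(lfc_raw, lfc_corr)> / (sqrt(2)*||.||)` —
  the mean angular (cosine) distance of (before, after) logFC pairs from
  the identity line; range [0, 2], 0 for a faithful correction.  The sum
  runs over all simulated DE genes with finite logFC in both tables
  (detected-only mode behind a flag); zero-norm pairs are dropped and
  counted.
* **Cumulative score / pAUC**: the running normalized sum of
  standard-positive weights along the ranking; pAUC is the mean of the
  curve over the top `floor(0.2 * u_max)` ranks (so a curve pinned at 1
  gives 1 — normalization preserves within-study ordering).
* **Truncated weighted KS**: the empirical cdf accumulates normalized
  positive weights along the ranking; beyond rank `N = floor(0.2 * u_max)`
  it is replaced by the straight line to 1, so
  `D+ = max(bridged cdf - u/u_max)` can only arise in the top ranks.  The
  right-tailed p-value permutes which ranks carry the weight multiset
  (default 10,000 permutations, add-one correction `(b+1)/(m+1)`).
  Because the bridge is anchored at zero discrepancy at the last rank, the
  statistic has an atom at exactly 0 under the null (a ranking whose
  positives never lead the uniform cdf in the window); those datasets get
  p = 1.  The left tail of the null p distribution is exactly uniform; the
  atom only makes the test conservative and shrinks as the positive set
  grows (~0.2 at 20 positives among 200 genes, ~0.05 at 400 among 2000).
* **False-call counts**: numbers of genes with p < 0.05 and q < 0.05 on
  null designs, plus the 5%-of-genes reference.
* **Rank similarity**: Spearman correlation of signed-score vectors on the
  common gene set.

## PVCA (`pvca`)

Cells x genes values are gene-centered and reduced by PCA; components are
retained until cumulative explained variance reaches 0.6 (capped at 20).
Each component's scores are decomposed into batch, group, batch x group
and residual variance; per-factor components are normalized per component
and averaged with weights proportional to explained variance.  An optional
random cell subsample bounds the cost on large data.

The per-component decomposition defaults to expected-mean-squares ANOVA
(negative components truncated at 0), not REML: with few factor levels the
REML likelihood is nearly flat along the batch-versus-interaction
direction and can split a pure batch shift between the two, whereas the
moment estimator attributes it entirely to batch and is deterministic.
REML (with moment fallback on failure) remains available via
`estimator="reml"`.  The moment estimator uses the average cell count per
batch x group as the balanced-design replicate number; it is exact for
balanced designs and approximate otherwise.

## Grading (`grading`)

All category rules use strict inequalities on both sides; boundary values
are Intermediate.

* Detection: Good iff truncated-KS p < 0.01 and pAUC rank <= 10 (min-rank
  over the evaluated workflow set); Poor iff p > 0.01 or rank > 20.
* FP/FD control: from repeated null-split runs at a low and a moderate
  depth — Good iff zero median false discoveries and median false
  positives <= 5% of genes at both depths; Poor iff positive median false
  discoveries at both and > 5% false positives at either.
* Sign preservation: `P = 100 * |median_a - median_b| / OVS`, with the
  overall visible spread defined as the span between the lowest and
  highest Tukey whisker (1.5 IQR, clipped to data) across both groups —
  the boxplot-vocabulary reading.  Good P < 30, Poor P > 60.
* Speed: Good if the large-fixture runtime < 600 s; Poor if the small
  fixture takes > 1800 s or the large one > 10800 s.  Runtimes are
  user-supplied and the thresholds configurable, since they are
  hardware-dependent.
* Scalability: one-parameter least squares through the origin of runtime
  against `sqrt(cells * genes)`; Good alpha < 1, Poor alpha > 2.

`run_benchmark` executes or ingests every declared workflow on every
fixture from a YAML/dict config, validates external result paths before
computing anything, and emits the metric table, the grade table and a
provenance record.  Re-grading is a pure function of the stored metrics.

## Problem sizes and defaults

The package's default problem sizes are desk-scale by design: simulations
of ~1000 genes and ~1050 cells (two batches of 300 and 750) reproduce the
benchmark geometry while keeping every test and the acceptance script
runnable in minutes on one CPU.  Statistical calibration checks use 1000
null genes (binomial 99% CI around the 5% level) and 200-replicate
permutation-null studies.  Seeds are explicit everywhere; all stochastic
assertions state their tolerance next to the sampling error they allow.
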