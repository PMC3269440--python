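# Methods

## The problem

Microarray expression measurements carry systematic processing noise —
batch effects — introduced at every stage of the sample-preparation
workflow: separate experiments (new amplification/labelling rounds),
processing runs (days), chips, and array positions. When batches are
confounded with biology this noise can fabricate or erase differential
expression. `batchscope` implements the full analysis loop for studying
this structure: a generative model of nested batch noise, per-probe
variance-component estimation, empirical-Bayes probe-wise correction,
evaluation of inter-batch calibrator samples, probe-composition
vulnerability analysis, and a differential-expression concordance check.

## Generative model

All quantities live on the log2-intensity scale. For probe *g* on
array/sample *j*,

    y_gj = mu_g + beta_g(group(j)) + sum_l  b[unit(j,l), g] * v_l(g) * w(g,j) + eps_gj

* `mu_g` — per-probe baseline, Normal(8.0, 1.5²); the range of typical
  BeadChip log2 intensities.
* `beta_g` — fixed group effect. The first group is the reference (zero);
  in other groups a configured fraction of probes receives a
  Normal(0, effect_sd²) log2 effect.
* `b[u, g]` — random effect of batch unit *u* at level *l* (experiment ⊃
  run ⊃ chip), drawn Normal(0, sd_l²) independently per (unit, probe). One
  sample per array; the array is the residual-bearing unit
  (eps ~ Normal(0, residual_sd²)).
* `v_l(g)` — GC-vulnerability multiplier: a step function equal to
  `multiplier` when the probe's GC fraction is below the cutoff (default
  0.55) at the configured levels, else 1. Low-GC probes hybridise less
  stably, making them more sensitive to batch conditions; the step form
  keeps the mechanism transparent and testable.
* `w(g,j) = (1-kappa) + kappa * s(g,j)` — expression-coupling weight,
  where `s` maps the probe's *true* (noise-free) expression to [0, 1] by
  within-sample rank. With `kappa > 0` a sample's batch response depends on
  its own expression profile, which is the mechanism that lets pooled
  calibrators (whose profile matches the samples) track sample-specific
  batch shifts better than a generic control RNA. The rank map is a
  deliberately minimal monotone choice; the real mechanism (hybridisation
  chemistry) is not modelled.

Default level SDs are 0.30 / 0.15 / 0.10 (experiment / run / chip) with
residual 0.20: noise decreasing from outer to inner levels, i.e. the
earlier a step sits in the workflow, the more variation it contributes.

**Controls.** A generic control (UHRR-like) carries one fixed profile drawn
independently of the biological samples and is replicated across chips. A
pooled control carries the arithmetic log2 mean of its member samples' true
profiles (a well-mixed approximation to physically pooling RNA; pools cycle
over the biological groups). Technical duplicates share one source profile
and are hybridised in two distinct units of a configured level (default:
run), with independent batch and residual draws.

**Detection confidences** are `sigmoid(1.5 * (true + N(0, 0.5²) - 5.5))`:
monotone in expression, so dim probes fail detection. With baselines at
Normal(8, 1.5²) roughly half of probes survive the standard filter, the
ballpark observed on real BeadChip data.

**Canonical designs.** `replicate_control_design` fills a balanced
3 experiments × 2 runs × 2 chips × 2 arrays grid with replicates of one RNA
source (24 arrays). `tumour_duplicate_design` emulates a paired-biopsy
follow-up experiment: 2 runs × 2 chips × 12 arrays, 14 duplicated sources
split across the runs, 6 generic controls, 8 pooled controls (pre/post
pools on every chip), and 6 non-duplicated samples in two groups.
Group samples are interleaved across consecutive arrays so every batch is
blocked (no group/batch confounding by construction).

## Preprocessing

*Detection filter*: a probe is removed when its confidence is **≤** the
threshold (default 0.95) in **strictly more than** `max_fail_fraction`
(default 20%) of samples — both boundaries deliberately strict, and the
filter runs before normalisation. *Quantile normalisation* replaces each
rank's value by the cross-sample mean of that rank's order statistics; tied
input values receive the mean of the reference values at their tied ranks,
which makes the operation idempotent and deterministic. Background
correction is deliberately omitted (it rescales magnitudes without changing
the relative variance structure); `quantile_normalize` operates on whatever
matrix it is given, so a background step can be inserted upstream.
Correlations are Pearson product-moment, reported as percentages.

## Variance decomposition

Each probe is fitted with a nested (hierarchical) Gaussian variance model:
biological variables as fixed effects, processing levels as nested random
effects. Two estimators:

* `fit_nested_mom` — classical expected-mean-squares ANOVA for balanced
  designs: stratum mean squares solved through the triangular EMS system,
  vectorised across probes. Negative solutions are truncated to zero in the
  reported SDs; the signed solutions are retained for diagnostics.
* `fit_nested_reml` — REML over nonnegative components. On balanced
  designs the stratum sums of squares are sufficient statistics and the
  restricted likelihood is `sum_l df_l log w_l + SS_l / w_l` with
  `w = C sigma²` (C the EMS coefficients); when the EMS solution is
  interior it *is* the REML optimum and is returned directly, otherwise a
  bound-constrained L-BFGS-B run (analytic gradient) finds the boundary
  solution. Unbalanced designs use the dense restricted likelihood with
  per-component analytic gradients. Optimisation is done directly on the
  variance scale with a zero lower bound rather than on log-variances:
  boundary zeros are then exact, and the balanced-case optimum coincides
  with the EMS solution without any reparameterisation. A fixed factor is
  handled by per-group centring on balanced designs (where it is orthogonal
  to the batch strata) and by GLS in the dense path.

Degenerate cases: an all-equal probe returns zero components (converged);
a level with a single unit is inestimable and reported absent; zero-variance
probes are flagged and skipped by `decompose`, which never aborts the batch.

**Two cross-probe summaries.** The percent contribution of a level is
`100 * meanSD_l / sum_k meanSD_k` over per-probe SDs — the SD-scale sharing
rule used for the headline percentages. For *recovery* of generative SDs the
right quantity is the pooled estimator (probe-summed stratum sums of squares
solved once, square root last): the mean of per-probe SDs is biased ~15% low
at 2–3 degrees of freedom purely by Jensen's inequality, and truncated
per-probe variances are biased high for near-zero components, whereas the
pooled estimator is unbiased on the variance scale. Both are reported in
`VarianceDecomposition` (`mean_sd`/`percent` vs `pooled_sd`).

## Empirical-Bayes batch correction

Three stages, per batch level:

1. **Standardise.** Per probe, least squares on batch indicators plus
   optional covariates; the grand location is the batch-size-weighted mean
   of the batch coefficients, so the raw additive estimates satisfy
   `sum_i n_i gamma_hat_ig = 0`. The pooled variance divides by N. Samples
   lacking a covariate value (controls without a biological group) form
   their own covariate level instead of erroring.
2. **Hyperpriors by moments.** Per batch, the cross-probe mean/variance of
   `gamma_hat` give a Normal prior; the cross-probe mean m and variance V of
   `delta_hat²` give an inverse-gamma prior via `lambda = 2 + m²/V`,
   `theta = m (lambda - 1)`.
3. **Posterior expectation.** Iterate the conditional posterior means of
   `gamma*` and `delta*²` (initialised at the raw estimates) until the
   maximum absolute change falls below 1e-6, capped at 100 iterations. The
   adjustment is `sigma_g / delta*_ig * (z_gj - gamma*_ig) + stand_mean_gj`.

Full batch/covariate confounding raises an error rather than silently
removing the biology. Two-level correction runs sequentially, outermost
level first. Probes with zero residual variance (e.g. rank-stable probes
after quantile normalisation) cannot be standardised; their batch means are
aligned through the location model and no scale adjustment is applied, and
they are listed in `passthrough_probes`.

Note that the posterior-mean adjustment is a *contraction*, not a
projection: with n samples per batch roughly `delta*²/(n tau² + delta*²)`
(≈ ½ at n = 10) of each probe's per-batch sampling deviation survives one
pass, so re-fitting on corrected data produces small further changes —
orders of magnitude below the first pass, but not machine zero. The
parametric variant only is implemented; the nonparametric prior is out of
scope. Mean-centring (subtract batch mean, add grand mean) is provided as
the baseline method and equals the EB correction in the no-shrinkage,
no-scale limit.

## Calibrator evaluation

A *shift* is the per-probe log2 difference of the same RNA across two
batches, with signs oriented by lexicographic batch-label order so that
sample and control shifts cancel consistently in correlations. Duplicate
ids with more than two samples contribute every cross-batch pairing;
same-batch pairs are skipped with a warning. Fidelity is the Pearson
correlation (as %) between a control pair's shift and a duplicate pair's
shift, overall and restricted to probes whose |sample shift| exceeds
cumulative thresholds (default 0, 0.5, 1.0, 1.5 log2 units; underpopulated
bins are reported absent, not zero). Calibrator types are compared by a
one-sample two-tailed t test on the paired per-duplicate differences;
zero-variance nonzero differences are degenerate (p = NaN).
"Batch-regulated" probes are those with |shift| strictly above
log2(fold_threshold) in at least `min_pairs` duplicate pairs — both
inequalities strict, so a shift of exactly 1.0 log2 at threshold 2-fold
does not count.

## Probe properties

GC/SD enrichment cross-tabulates (GC < 0.55) × (SD > cutoff) and applies
Pearson's chi-squared without continuity correction; the SD cutoff defaults
to the 90th percentile of the SD vector, which adapts per level and makes
the result invariant to monotone transforms of the SDs. Expected cell
counts below 5 flag the result unreliable (still returned). Distribution
shifts of a probe subset are assessed by Gaussian-kernel densities (fixed
absolute bandwidth, default 0.02) plus a chi-squared goodness-of-fit test
of the subset's binned counts (width 0.05) against universe proportions;
subsets under 20 probes are flagged underpowered. Probe-position trends use
Spearman correlation with a seeded permutation p (1,000 permutations);
positions are assumed strand-normalised (antisense fractions flipped to
1 − raw) upstream.

## Differential expression

Plain t tests (Welch for two groups, paired via a pairing column) with
Benjamini–Hochberg adjustment; a probe is significant when the adjusted p
is ≤ 0.01 *and* the natural-scale fold change satisfies `2^|log2fc| ≥ 1.5`.
Moderated-t and permutation-FDR machinery is intentionally not reproduced:
the quantity of interest here (how list concordance responds to batch
correction) is method-agnostic at simulation scale. An optional variance
floor (per-probe SD floored at the cross-probe median) is available for
small-sample stability, off by default. Probes with no within-group
variance carry no evidence (t = 0, p = 1).

## Study conditions and problem sizes

The studies in `batchscope.studies` (used by `tests/test_acceptance.py`,
`scripts/acceptance.py`, and the `analysis/` drivers) run at:

| study | size |
|---|---|
| variance recovery | 1,000 probes, 3×2×2×2 design, single REML pass |
| correction efficacy | 2,000 probes, 4 batches × 10 samples, additive N(0, 0.5²), scale LogNormal(0, 0.2²) |
| normalisation invariance | 1,000 probes, default replicate design |
| GC vulnerability | 100 replicates × 5,000 probes, ×2 multiplier at run level (and ×1 null) |
| calibrator ordering | 100 replicates × 1,000 probes, kappa 0.5 (and 0) |
| DE concordance | 20 replicates × 2 experiments × 1,500 probes |

These sizes give Monte-Carlo error comfortably inside each study's decision
band while keeping a full run to a couple of minutes on one CPU.

## What the simulations do and do not show

The generator reproduces the *structure* of multi-batch array studies —
nested Gaussian batch noise, duplicates, both calibrator types, GC-coupled
vulnerability, detection dropout — so passing studies demonstrate that the
estimators recover what was planted, that the correction removes what it
models, and that the qualitative orderings (outer levels noisier; pools
track samples better than generic controls when batch response is
expression-coupled; low-GC probes enriched for high SD) follow from those
mechanisms. It does not model image processing, background signal,
bead-level replication, spatial chip artefacts, dye/scanner physics, or
real hybridisation chemistry, so numbers measured here characterise the
model, not any particular platform or dataset.

## Known limitations

* The EMS estimator requires balance; unbalanced designs fall through to
  the dense REML path, which is slower (per-probe optimisation).
* Percent contributions inherit the truncation/Jensen biases of per-probe
  SDs at small unit counts; treat them as a sharing summary, not as
  unbiased component estimates (use `pooled_sd` for that).
* Sequential two-level EB correction is a pragmatic mirror of running the
  correction twice; it is not a joint two-level model.
* The expression-coupling weight is a stylised rank map; only its monotone
  direction, not its form, is supported by the data it emulates.
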