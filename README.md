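# batchscope

Systematic processing noise — batch effects — is endemic to expression
microarray experiments: separate amplification/labelling rounds, processing
runs, chips, and array positions each leave their own fingerprint on the
reported log2 intensities, and when these batches align with the biology
they can fabricate or erase differential expression. `batchscope` is a
toolkit for scientists who design, audit, or correct such experiments. It
provides:

* a **synthetic-data generator** for nested batch designs (experiment ⊃ run
  ⊃ chip ⊃ array) with technical duplicates, generic (UHRR-like) and pooled
  control samples, GC-dependent probe vulnerability, and expression-coupled
  batch response — with full ground truth for estimator validation;
* **per-probe nested variance decomposition** (expected-mean-squares and
  REML estimators) reporting the SD each processing level contributes;
* **empirical-Bayes probe-wise batch correction** (location/scale model
  with moment-matched Normal and inverse-gamma priors and posterior-mean
  shrinkage) plus a mean-centring baseline;
* **calibrator evaluation**: how faithfully control replicates track the
  batch shifts of duplicated samples, pooled vs generic controls;
* **probe-property analyses** (GC×SD enrichment, position trends) and a
  fold-change + BH **differential-expression** stage with list-concordance
  summaries.

## The model in brief

Per probe *g* and sample *j* (log2 scale):

    y_gj = mu_g + beta_g(group_j) + sum_l b[unit(j,l),g] · v_l(g) · w(g,j) + eps_gj

with nested random batch effects `b ~ N(0, sd_l²)`, GC-vulnerability step
`v_l(g)` (low-GC probes get inflated batch SD), expression-coupling weight
`w = (1-kappa) + kappa·s(true expression rank)`, and residual
`eps ~ N(0, sd_e²)`. Variance components are estimated per probe by REML
(EMS as the balanced-design oracle) and reported on the SD scale; percent
contributions are `100 · meanSD_l / Σ_k meanSD_k`. The batch correction
standardises each probe, estimates per-batch additive/multiplicative
parameters, shrinks them toward cross-probe moment-matched priors, and
adjusts by the posterior means. See `docs/methods.md` for the full account.

## Worked example

```bash
python analysis/01_simulate.py --seed 1          # two synthetic datasets
python analysis/02_preprocess.py                 # detection filter + QN
python analysis/03_variance_components.py        # nested REML decomposition
python analysis/04_batch_correction.py           # EB correction, 2 levels
python analysis/05_calibrators.py                # pooled vs generic controls
```

which prints (seed 1):

```
percent contribution per level (mean per-probe SD):
  experiment    38.2%   pooled SD 0.301 (generative 0.30)
  run           18.5%   pooled SD 0.153 (generative 0.15)
  chip          12.9%   pooled SD 0.105 (generative 0.10)
  residual      30.4%   pooled SD 0.205 (generative 0.20)
[normalized]            pooled SDs experiment=0.301, run=0.153, chip=0.105 ...; median replicate correlation 83.8%
[combat_experiment]     pooled SDs experiment=0.000, run=0.137, chip=0.096 ...; median replicate correlation 94.5%
[combat_experiment_run] pooled SDs experiment=0.000, run=0.000, chip=0.078 ...; median replicate correlation 97.0%
14 duplicate pairs: pooled - generic = +5.97 percentage points (one-sample two-tail t test p = 1.84e-10)
```

Reading this: the outermost level (experiment, i.e. a fresh
amplification/labelling round) contributes the largest share of technical
SD and the pooled estimates recover the generative SDs (0.30/0.15/0.10/0.20)
within a few percent. Correcting by experiment and then by run removes
those components entirely and lifts replicate correlations from 84% to 97%.
Pooled calibrators, whose expression profile matches the samples they
accompany, track the duplicated samples' batch shifts about 6 correlation
points better than a generic control RNA when batch response is
expression-coupled. `analysis/06_probe_properties.py` and
`analysis/07_differential_expression.py` continue with the GC-enrichment
(significant at the experiment and run levels, not at chip) and
DE-concordance (intersection of DE lists across replicate experiments grows
after correction) analyses.

The same stages are available as a CLI (`batchscope simulate | preprocess |
decompose | correct | calibrate-eval | probe-props | de | run`) and as a
single configured pipeline (`batchscope run --seed 1 --out-dir out/`), which
writes a deterministic `report.json`.

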