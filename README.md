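# mrprev

Small-area prevalence estimation for a binary behaviour by geographic
domain, time point and demographic subgroup, using multilevel regression
and post-stratification (MrP):

1. **Step 1 — multilevel regression.** Nine candidate weighted logistic
   mixed models (linear, categorical and piecewise-linear time trends;
   domain, race-within-domain and wave random intercepts) are fit by a
   Laplace-approximate marginal likelihood and compared by AIC/BIC.  The
   selected model predicts the outcome probability for all 72
   sex × age × race/ethnicity × SES cells in every domain and time point.
2. **Step 2 — post-stratification.** Cell predictions are averaged with
   weights from a post-stratification frame of smoker totals, built from
   a smoking-status survey and a population census via a
   variance-weighted composite of direct and model-smoothed estimates,
   small-cell fallback rules, and iterative proportional fitting to the
   survey's single-factor margins.

Percentile bootstrap confidence intervals (resampling respondents within
domain × wave, refitting the selected model per replicate) and
concordance-based validation against an independent gold survey round
out the pipeline.  A fully seeded synthetic-data module generates all
four input surveys plus ground truth, so every estimator can be scored
against known values.

## Layout

| module | contents |
| --- | --- |
| `mrprev.design` | demographic cells, SES composite, labor-force centering, time bases, the nine model specifications, design matrices, parameter counts |
| `mrprev.synthetic` | seeded data-generating process: population census, outcome survey, smoking survey, gold survey, truth table |
| `mrprev.glmm` | weight rescaling, Laplace-approximate mixed-model fitting, cell prediction, AIC/BIC model selection |
| `mrprev.frame_builder` | direct/model/composite smoking estimates, fallback rules, smoker totals, IPF raking |
| `mrprev.poststratify` | weighted aggregation to domain/wave/subgroup prevalence |
| `mrprev.uncertainty` | stratified resampling, percentile intervals, bootstrap pipeline |
| `mrprev.validation` | concordance correlation (precision × accuracy), agreement reports, recovery metrics |
| `mrprev.cli_io` | typed CSV I/O, YAML configuration, pipeline driver, CLI |

## CLI

```sh
mrp-prev all --config config.yaml            # simulate + full pipeline
mrp-prev simulate --config config.yaml       # write synthetic inputs only
mrp-prev estimate --config config.yaml       # pipeline without bootstrap
mrp-prev bootstrap --config config.yaml --replicates 1000
mrp-prev validate --config config.yaml
```

Example configuration:

```yaml
simulate:            # omit and set data_dir to run on existing tables
  n_domains: 3
  n_waves: 4
  n_outcome: 500     # respondents per domain-wave, outcome survey
  n_smoking: 2000
  n_gold: 2000
seed: 1
out: runs/demo
bootstrap: {replicates: 1000, alpha: 0.05, seed: 1}
```

Outputs are plain CSV/JSON: `cell_predictions.csv` (72 · domains · waves
rows), `frame.csv`, `margins.csv`, `estimates.csv` (long format with
bootstrap bounds), `validation.csv`, `recovery.json`, and the fitted
model summaries.

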