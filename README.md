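# trajarea

Analysis toolkit for two-arm longitudinal trials with repeated, correlated
outcome measures and incomplete records:

- **Synthetic trial generator** (`trajarea.config`, `trajarea.generator`):
  synthetic two-arm trial datasets (default 28/26
  split over occasions at 9/15/27/39 months) with per-instrument observed
  scales (count-like symptom totals, 1–7 interaction ratings, proportions,
  T-/standard scores), cross-occasion latent correlation, an instrument
  switch mid-series, configurable standardized treatment-effect curves, and
  missed-visit missingness (MAR given arm × occasion).
- **Joint ML estimation** (`trajarea.sur`): occasion-specific
  treatment-effect regressions with correlated errors, estimated by
  full-information maximum likelihood so participants with incomplete
  outcome records still contribute.  GLS/EM alternation with a monotone
  likelihood path; joint coefficient covariance with a small-sample
  degrees-of-freedom adjustment.
- **Effect trajectories and areas** (`trajarea.effects`): per-occasion
  Cohen's d via pooled within-group SDs (optionally stratified, e.g. by
  assessment module), baseline-anchored at d = 0, combined into a
  trapezium-rule area between curves with a Wald z test, plus a
  leave-one-participant-out sensitivity utility.
- **Bootstrap CIs** (`trajarea.resampling`): percentile intervals from
  participant resampling with replacement, stratified within arm.
- **Categorical statistics** (`trajarea.categorical`): exact 2×K
  Freeman–Halton test by full enumeration, proportional-odds ordinal
  logistic regression (Newton iteration), and ICC(1,1) / ICC(A,1)
  coder-reliability coefficients.
- **Pipeline + CLI** (`trajarea.pipeline`, `trajarea.cli`): reproducible
  end-to-end runs over multiple outcome domains with JSON/Markdown reports
  and SVG trajectory plots.

## CLI

```sh
# generate a synthetic trial (defaults calibrated to the published summary table)
trajarea simulate --seed 7 --out trial.csv

# fit the joint occasion regressions described in a YAML occasions list
trajarea fit --data trial.csv --config occasions.yaml --out fit.json

# standardized trajectory + area-between-curves with Wald test
trajarea area --data trial.csv --config occasions.yaml --out area.json --plot area.svg

# bootstrap CI for the area, resampling participants within arm
trajarea bootstrap --data trial.csv --config occasions.yaml -B 1000 --seed 11 --out boot.json

# exact test + ordinal OR on a 2x3 diagnostic table
trajarea diagnose --table 16,8,2:16,7,4

# coder-reliability ICCs from a ratings CSV (one column per coder)
trajarea reliability --data ratings.csv

# full multi-block pipeline
trajarea run --config analysis.yaml
```

An occasions config looks like:

```yaml
anchor_time: 9
occasions:
  - {label: t15, time: 15, outcome: aosi_15, baseline: aosi_9,
     covariates: [centre, age_15, ethnicity, maternal_education]}
  - {label: t27, time: 27, outcome: ados_27, transform: log1p, baseline: aosi_9,
     covariates: [centre, age_27, ethnicity, maternal_education]}
  - {label: t39, time: 39, outcome: ados_39, transform: log1p, baseline: aosi_9,
     covariates: [centre, age_39, ethnicity, maternal_education],
     sd_stratum: ados_module_39}
```

## Data format

Wide CSV, one row per participant; missing cells are empty. Fixed columns
`participant_id, arm, centre, maternal_education, ethnicity,
diagnostic_outcome`; everything else is `name_<months>` (e.g. `aosi_9`,
`ados_27`, `ados_module_39`, `maci_nondir_15`, `dcma_sync_39`, `age_15`).
`trajarea.dataset.read_dataset` validates ranges (MACI in [1,7], DCMA in
[0,1], ages strictly increasing, ...) and reports *all* violations at once.
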