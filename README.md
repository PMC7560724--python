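# qoli

Quality of Life Index toolkit: computes actual, theoretical, and Lost
QALYs from longitudinal health-utility observations collected during
neoadjuvant treatment, combines Lost QALY with Residual Cancer Burden
(RCB) into a single signed composite score, and summarizes and compares
trial arms. A synthetic multi-arm cohort generator makes every stage
testable without access-restricted trial data.

## Method

Patients contribute a health utility (bounded in [-0.022, 1.0]) at three
timepoints: baseline, pre-surgery, and one month post-surgery.

- **Actual QALY** — area under the utility-versus-time curve over a fixed
  6-month window (piecewise-linear interpolation by default, last
  observation carried forward to the window end).
- **Theoretical QALY** — baseline utility held constant over the window.
- **Lost QALY** — theoretical minus actual; negative values are net gains.
- **Composite score (QoLI)** — `-(rcb / 4.35 + lost_qaly / 0.54)`; higher
  means better quality-of-life-adjusted clinical efficacy. The
  normalization denominators are study-derived maxima and overridable.

Analysis is complete-case by default: only patients with all three
timepoints are scored. Utilities may be supplied directly or derived from
seven standardized PROMIS-style domain T-scores via a pluggable scorer
(the published preference-based scorer is *not* bundled; a documented
rescaled-mean stub exists for end-to-end testing), with optional OLS
imputation of missing domains.

## CLI

```sh
# 1. generate a synthetic two-arm cohort from a YAML arm-spec file
qoli simulate --specs specs.yaml --out-dir cohort --seed 1

# 2. score patients: complete-case filter -> QALYs -> composite scores
qoli compute --pro cohort/pro.csv --efficacy cohort/efficacy.csv --out-dir out

# 3. arm-level summaries, density grids, and bootstrap comparisons
qoli summarize --results out/patient_results.csv --out-dir summary --boot 2000 --seed 1
```

Exit codes: 0 success, 2 input-validation failure, 3 configuration error.
All tables are comma-separated UTF-8 text with a header row. An arm-spec
file looks like:

```yaml
arms:
  - arm: control
    n_patients: 100
    baseline_mean: 0.82
    dip: 0.15              # mean utility decrement at pre-surgery
    recovery_fraction: 0.7 # fraction of the dip regained post-surgery
    pcr_prob: 0.3          # point mass of RCB at 0
    completion_prob: [1.0, 0.43, 0.43]
```

`qoli compute --config cfg.yaml` accepts a key-value YAML overriding the
window (`window_years`), integration policy (`integration`, `extension`),
and normalization constants (`max_rcb`, `max_lost_qaly`).

## Layout

| module | contents |
|---|---|
| `qoli.core_model` | trajectories, QALY integration |
| `qoli.qoli_index` | normalization and composite score |
| `qoli.utility_scoring` | domain profiles, pluggable scorers, OLS imputation |
| `qoli.arm_summary` | per-arm statistics, KDE density export, bootstrap contrasts |
| `qoli.synthetic_cohort` | seeded multi-arm cohort generator with missingness |
| `qoli.cli_io` | file formats, configuration, pipeline, CLI |
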