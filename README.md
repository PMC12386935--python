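# agestage

Age-stage, two-sex life table analysis for daily-census cohort rearing
data: survival and fecundity schedules, demographic parameters,
bootstrap inference, paired-bootstrap cohort comparison, age-stage
population projection, and bi-choice preference statistics — plus a
synthetic cohort generator with analytic ground truth.

## What it computes

From a cohort of individuals followed daily from oviposition (age 0) to
death, the package derives:

- **Schedules** — age-stage survival `s_xj`, age-specific survival
  `l_x`, per-stage fecundity `f_xj`, age-specific fecundity `m_x`, net
  maternity `l_x m_x`, life expectancy `e_xj`, reproductive value `v_xj`.
- **Parameters** — net reproductive rate `R0`, intrinsic rate of
  increase `r` (root of the discrete renewal equation
  `sum_x exp(-r(x+1)) l_x m_x = 1`, solved to a residual below 1e-10),
  finite rate `lambda = e^r`, mean generation time `T = ln(R0)/r`, and
  cohort summaries (stage durations, APOP/TPOP, oviposition days,
  fecundity per female, sex-composition proportions, supernumerary-instar
  proportion).
- **Uncertainty** — bootstrap SEs and percentile CIs with the individual
  as the resampling unit (default 100,000 resamples), and a two-sided
  paired bootstrap test for between-cohort differences.
- **Projection** — deterministic expected-value propagation of an
  initial egg cohort through the empirical daily transition model, with
  bootstrap 95% bands; a stochastic individual-based mode is available
  for cross-validation.
- **Preference** — water-loss-corrected consumption proportions and
  egg-batch proportions for bi-choice assays, tested with the Quade
  randomized-block test (F approximation, with exact-permutation
  fallback and an explicit exact mode).
- **Synthesis** — `synthetic_cohorts` generates cohorts from configured
  stage-duration, survival, and fecundity distributions and reports the
  analytic `R0`/`r` implied by the configuration, enabling parameter
  recovery experiments.

## Cohort file format

One CSV row per individual per day: `id,day,stage,eggs,sex`. Stage
labels follow the default schema `EGG, L1..L8, PUPA, ADULT_F, ADULT_M`
(`L7`/`L8` are optional supernumerary instars). `sex` is `female`,
`male`, or `unknown` (pre-adult deaths). `eggs` is blank or 0 except on
laying days of adult females. Days must be consecutive from 0; the last
row is the last day alive.

## CLI

```sh
agestage simulate --preset faw-like --seed 7 --out cohort.csv
agestage lifetable cohort.csv --out-dir results/
agestage compare a.csv b.csv --param fecundity --B 2000 --seed 1
agestage project cohort.csv --eggs 10 --days 120 --B 200 --seed 1
agestage preference feeding.csv --mode feeding
```

Presets: `faw-like`, `corn-like`, `jobs-tears-like`, `well-mixed`;
`simulate --config cfg.yaml` accepts a YAML configuration (see
`agestage.synthetic_cohorts.save_config`). Every stochastic subcommand
requires `--seed` and is byte-reproducible given one.

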