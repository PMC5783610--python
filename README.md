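# nmrsurv

Survival and mortality-hazard demography for censored animal-colony
lifespan records, built around the question of whether a species' mortality
follows the Gompertz-Makeham law of aging,

    h(t) = α e^(βt) + γ,

or stays flat with age — the constant-hazard (exponential-decay) regime in
which the meaningful lifespan summary is a demographic half-life,
ln 2 / λ, rather than a maximal lifespan. The motivating organism is the
naked mole-rat (*Heterocephalus glaber*), whose captive-colony records
show no detectable rise in the per-day probability of death even decades
past reproductive maturity (T_sex = 183 days), but every component works
on any common-entry, right-censored lifespan data.

The package is aimed at biogerontologists and biodemographers working with
historical colony spreadsheets: records with mixed-resolution dates
(month-of-birth, "Fall 1999", ">1997"), heavy and structured
right-censorship (animals transferred, sacrificed for research, or still
alive at compilation), and partially unlabeled breeder status.

## What it does

* **records_io** — parses colony spreadsheets, imputes low-resolution
  dates by deterministic midpoint rules (15th of the month; July 2 of the
  year; Nov 7 for Fall; range midpoints; nearest date satisfying an
  inequality), classifies censorship (alive-at-compile, sold, killed for
  research), and emits post-maturity observations at four nested
  date-resolution stringency tiers with full row accounting.
* **survival_hazard** — Kaplan-Meier curves; per-age-bin hazards as
  deaths ÷ exposure animal-days with continuity-corrected Wilson score
  intervals; the same estimator for censorship probability; fixed-width,
  explicit-edge and adaptive (even-CI) binning; median / 95th-percentile
  lifespan summaries.
* **demographic_models** — Gompertz-Makeham closed forms, censoring-aware
  maximum-likelihood fits, likelihood-ratio comparison against the
  constant model, species life-table ingestion (human, horse, mouse) with
  survival rebuilt by iterative multiplication, and re-scaling of hazard
  trajectories to multiples of each species' T_sex.
* **cohort_simulator** — per-day censor-then-death Bernoulli simulation
  under age-binned probabilities per stratum (breeder / non-breeder),
  100-simulation envelope summaries, and the hidden-breeder mixture
  experiment.
* **synthetic_data** — ground-truthed synthetic colony collections
  (queens, 1–3 breeding males per colony, mislabeled male breeders, a
  birth-year pulse that becomes a censorship pulse at the compile date,
  stochastic date degradation) for end-to-end calibration testing.
* **cli** — the `nmrsurv` command with `parse`, `km`, `hazard`, `summary`,
  `fit`, `lifetable`, `simulate`, `mixture` and `synth` subcommands; every
  run writes a manifest for reproducibility.

## Worked example

Generate a synthetic colony collection, parse it at day-resolution
stringency, and estimate hazards and mortality models:

```sh
nmrsurv synth --out-dir colony --seed 1
nmrsurv parse colony/lifespans.csv --out-dir parsed --tier day
nmrsurv hazard parsed/observations.csv --observations --out-dir hz --mode adaptive
nmrsurv fit parsed/observations.csv --observations --out-dir fits
```

The generator prints `3290 records written`; parsing keeps
`3084 observations` (206 animals died or were censored before day 183 and
are excluded with logged reasons). The first rows of
`hz/hazard_death.csv`:

```
bin_start,bin_end,events,exposure_days,hazard,ci_low,ci_high,n_start
183,400,121,631864,0.000191,0.000160,0.000230,3084
400,505,30,281000,0.000107,0.0000733,0.000154,2741
505,622,30,297468,0.000101,0.0000693,0.000146,2607
```

The elevated first bin (1.9 × 10⁻⁴ deaths/day over [183, 400)) and the
flat ~1 × 10⁻⁴/day thereafter recover the generator's true model
(2 × 10⁻⁴ early, 1 × 10⁻⁴ adult). The fit output reports the constant
MLE λ̂ = 1.04 × 10⁻⁴/day (609 deaths over 5.85 million observation days)
and a likelihood-ratio statistic of 22.7 for the Gompertz alternative with
*negative* β — the fit detects the early-life hazard decline, not aging;
on cohorts without the elevated early bin the statistic drops below the
χ²₁ 95% cut. A hazard of 1 × 10⁻⁴/day corresponds to a demographic
half-life of ln 2 × 10⁴ ≈ 6931 days (about 19 years):

```python
>>> from nmrsurv import constant_hazard_median
>>> constant_hazard_median(1e-4)
6931.471805599453
```

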