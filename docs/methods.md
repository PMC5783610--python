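# Methods

`nmrsurv` is a demographic analysis pipeline for captive animal-colony
lifespan records — built around the naked mole-rat (*Heterocephalus
glaber*), whose mortality the package lets you test against the
Gompertz-Makeham law versus a constant-hazard (exponential-decay)
alternative. This note documents the models, the estimation conventions,
the simulation machinery, and the design choices made where the problem
left the design open.

## The analysis clock and censorship

All analyses run on the day-of-life clock and begin at reproductive
maturity, T_sex = 183 days for naked mole-rats (constant
`nmrsurv.T_SEX_DAYS`). Records whose death or censorship falls strictly
before day 183 are dropped and counted; an event exactly at day 183 is
kept, since the exclusion applies to events *prior to* maturity. Lifespan
is the whole-day difference between resolved end and birth dates, 0-based
from the birth date.

Right-censorship applies in three situations: animals still alive when a
spreadsheet was compiled (censored at the compile date), animals sold or
given away (censored at transfer), and healthy animals killed for research
("KFR", censored at sacrifice). An animal carrying both a KFR label and a
death record is treated as censored — the label is authoritative — and the
conflict is logged.

## Date imputation and stringency tiers

Colony records store dates at mixed resolution. Each date parses into a
`DateSpec` and is imputed deterministically:

| recorded form        | imputed date                          |
|----------------------|---------------------------------------|
| month (e.g. 1995-06) | the 15th of the month                 |
| year (e.g. 1997)     | July 2 (fixed, leap years included)   |
| season + year        | Fall → Nov 7; Winter → Feb 5; Spring → May 6; Summer → Aug 6 |
| range A..B           | start + floor((end − start)/2) days   |
| two candidate dates  | midpoint, treated as a range          |
| inequality (>1997)   | nearest satisfying date (Jan 1, 1998) |

"Approximate" markers (`~June 1995`) are treated the same as the exact
form. Year endpoints of a range expand to the full span (Jan 1 – Dec 31).
The Fall midpoint anchors the season set; the other three seasons use the
analogous mid-season days. July 2 is fixed in leap years too — shifting it
by half a day would move no estimate visibly and would cost determinism.

Records are admitted at four nested stringency tiers — day-resolution
only; plus month; plus the bounded low-resolution forms (season, year,
range, two options); plus one-sided inequalities, the least reliable form
since the true date is unbounded in one direction. The observation set at
each tier is a superset of the previous tier's (tested as an invariant).

## Kaplan-Meier and interval hazards

Survival uses the product-limit estimator with ties at a day processed
deaths-before-censorings. The per-day mortality hazard over an age bin
[start, end) is

    h = D / E

where D counts death events in the bin and E the animal-days of
observation within it: animals alive across the bin contribute its full
width, animals exiting inside it contribute the days up to *and
including* the exit day. Exposure therefore conserves exactly: summed over
bins it equals the total post-entry observation days (+1 event day per
animal). Censorship hazard uses the identical estimator with the roles of
death and censorship exchanged.

Confidence intervals are Wilson score intervals with continuity correction
(Newcombe's closed form) on (D, E), clipped to [0, 1], at 95% by default.
Against 1000 binomial draws at n = 10,000, p = 1e-4, the interval's
empirical coverage is ~98% — conservative, as expected for the corrected
form at rare event rates.

Three binning modes exist: fixed width (e.g. 200-day windows starting at
day 200 with a partial [183, 200) stub; 50-day windows from day 50 with a
[42, 50) stub for mice), explicit edges (for exact replication of a known
layout), and adaptive — a fixed first bin [183, 400) capturing the
elevated early-adult hazard, then bins closed once they accumulate
`min_events_per_bin` (default 30) deaths, which keeps confidence-interval
widths roughly even as the population shrinks. The adaptive rule is a
package convention: any published bin layout can be reproduced with
explicit edges.

Death events are counted per animal (one death = one event), matching the
arithmetic of per-animal totals; a per-day-collapsed count is not offered
because no analysis here needs it.

## Mortality models

The Gompertz-Makeham hazard is h(t) = αe^(βt) + γ with α, γ ≥ 0, t on the
post-maturity clock in days. β is the rate-of-aging; ln 2/β is the hazard
doubling time (~7–8.5 years in humans). α = 0 or β = 0 degenerates to a
constant hazard, under which survival decays exponentially and the
meaningful summary is the demographic half-life ln 2/λ — e.g. λ = 1e-4/day
gives 6931 days (~19 years) — rather than a "maximal lifespan".

Fitting maximizes the right-censored continuous log-likelihood
Σ_deaths log h(t_i) − Σ_all H(t_i), with H(t) = α/β(e^(βt) − 1) + γt. The
constant model has the analytic MLE λ̂ = D / Σt_i. Gompertz (γ = 0) and
Gompertz-Makeham fits use L-BFGS-B on (log α, β[, log γ]) from three
starting slopes; β is unconstrained but flagged when |β| < 1e-8/day, and
β·t is guarded against overflow (explicit error, never a silent inf).
Nested model comparison uses the likelihood-ratio statistic against the
χ²(1) 95% cut; because β may take either sign, the test under a true
constant hazard rejects at roughly the nominal 5%.

Survival percentile summaries read the curve where S first reaches 0.5
(median) and 0.05 (the operational "maximal lifespan", i.e. the 95th
percentile of post-T_sex lifespans). A percentile the data never reach is
reported as *not achieved* — never extrapolated. The segment ratio
(maximal − median)/median quantifies how truncated the upper half of the
lifespan distribution is: small under Gompertzian aging, 1.0 under pure
exponential decay.

Cross-species life tables enter as CSV with either deaths/at-risk columns
(hazard derived as deaths ÷ at-risk) or a precomputed hazard column; both
are supported because published sources differ in what they print.
Combining tables pools numerators and denominators. Survival is rebuilt by
iterative multiplication of (1 − hazard) from T_sex (183 d naked mole-rat,
42 d mouse, 16 y human female, 3 y horse). Annual probabilities convert to
per-day hazard compound-wise ((1−q) = (1−h)^365.25) by default, with
simple division as an option. Hazard trajectories can be re-plotted on a
T_sex-multiples axis (ages divided by T_sex; hazard values untouched).

## Cohort simulation

A `SimulationModel` assigns each stratum (breeder / non-breeder)
contiguous age bins over [183, 12000) carrying per-day death and
censorship probabilities, with per-bin provenance tags recording the
source of each estimate (e.g. female-only death hazards, combined-sex
censorship). Each simulated day, every surviving individual draws first
against censorship, then — if not censored — against death; survivors at
day 12,000 are censored there. Per-day probabilities conserve exactly:
P(censor) + (1 − P(censor))·P(death) + (1 − P(censor))·(1 − P(death)) = 1.

The draws are vectorized across individuals within each day (two uniform
arrays per day) rather than looped individual-by-individual; the
distribution is identical, and one master `SeedSequence` spawning a child
stream per simulation makes every ensemble bit-reproducible for any
population size.

Ensembles (default 100 simulations) are summarised on a 50-day evaluation
grid as the 5th/25th/50th/75th/95th percentiles of simulated survival.
Simulations whose population hits 0% keep contributing zeros at every
later day — exclusion rules bias the envelope upward — and per-day counts
of simulations are reported alongside. `envelope_coverage` scores an
observed KM curve as the fraction of checkpoint days inside the 5–95%
band; a curve drawn from the same model covers ~90% by exchangeability.

The mixture experiment simulates n_total individuals of which
n_hidden_breeders secretly follow the breeder (≈10-fold lower-hazard)
model while all are reported unlabeled — the scenario in which breeding
males go unrecorded because breeder status was only catalogued for colony
founders. With 175 hidden breeders among 1747, the late-life
(post-day-4000) envelope median rises by ~0.05–0.07 survival over the pure
non-breeder ensemble.

The package-default model is deliberately simple and fully overridable:
non-breeder death 1e-4/day (2e-4/day in [183, 400)), breeder death
1e-5/day, censorship 3e-4/day for non-breeders vs 1e-4/day for breeders
(reflecting the higher research-sacrifice rate of non-breeders) with a
2e-3/day pulse in the 2250–2500-day bin. The elevated-first-bin and
censorship-pulse values are package defaults chosen to reproduce the
qualitative structure of a real colony history, not measured quantities.

## Synthetic collections

The generator emulates the record set the parser expects: ~55 colonies of
Poisson(60) animals, each with one queen and 1–3 breeding males; breeding
males mislabeled as non-breeders with probability 0.68 (so roughly two of
every three true male breeders are hidden, the regime the mixture
experiment probes); queens always labeled. Lifecourses are drawn by the
simulator's own per-day mechanics from day 0 (juvenile hazard 5e-5/day
before day 183) on the *true* strata. Birth years are uniform over
1982–2015 with 17% of births concentrated in a pulse year (2010); animals
still alive at their colony's compile date (one of April 14, April 20, or
May 17, 2016) are censored there, which reproduces the cohort-entry
censorship pulse at ~6 years of age without any explicit pulse parameter.
Pre-compile censorship splits 66/34 between KFR and sold/given-away
labels. Dates can be stochastically degraded to month / season / year /
range / inequality forms, always consistently with the truth (the true
date lies inside the degraded form's span, or satisfies the inequality).

Ground truth (true dates, true events, true breeder status) is written to
a `truth/` sidecar directory that the analysis path never reads.

What the generator does *not* emulate: colony genealogy and queen
succession, socially mediated (non-independent) mortality, weight and
husbandry covariates, multi-institution transfer history, and any true
late-life hazard decline. Tests passing on synthetic data therefore
establish the pipeline's estimator calibration and bookkeeping, not the
biology of any real colony.

## Problem sizes and numerical conventions

The test suite and acceptance script run the study at these sizes:
estimator-recovery coverage over 100 generated cohorts of ~1400–1500
analyzable animals each; likelihood-ratio discrimination over 100 aging
(α = 1e-5/day, β = 0.005/day) and 100 constant-hazard (λ = 1e-4/day)
cohorts of n = 2000; one n = 10,000 simulation for the half-life closed
form; and 100-simulation ensembles of n = 1747 for the mixture contrast.
Ties in KM are deaths-before-censorings; bins are half-open [start, end);
survival comparisons at a day use the step function just after that day;
all per-day probabilities are clipped nowhere — invalid inputs raise.

## Known limitations

* The continuous-likelihood fit treats day-grid durations as continuous;
  at hazards ≤ 1e-3/day the discretization bias is far below sampling
  error, but the geometric day-grid likelihood is not separately offered.
* No Cox regression, smoothing/spline hazard estimators, left truncation
  beyond the common entry day, or late-life mortality-deceleration models.
* The adaptive bin rule and the default simulation model's censorship
  pulse are package conventions, not estimates from any dataset.
* `fit_mortality_model` requires at least one death; all-censored data are
  an error by design.
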