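# Methods

`diabem` implements a desk-scale diabetes burden-estimation chain: from
synthetic epidemiological inputs through compartmental consistency
modelling, death-type redistribution, DALY accounting, risk-attributable
burden, and prevalence forecasting, with Monte-Carlo draws carried end to
end. This note records the models, their assumptions, the numerical
choices, and what the synthetic test-bed does and does not demonstrate.

## The illness-death model (`diabem.epi`)

A birth cohort is tracked along age `a` at a fixed calendar year (a
period approximation — no cohort crossing of calendar years), with a
susceptible fraction `S(a)` and a case fraction `C(a)`:

    dS/da = -(i + m) S + r C
    dC/da =  i S - (r + m + f) C

where `i` is incidence, `r` remission, `f` excess mortality among cases
and `m` background (non-diabetes) mortality, all per person-year.
Prevalence is `p = C/(S+C)` and the cause-specific mortality rate is
`csmr = p·f`, so the five measures returned by `solve_illness_death` are
consistent by construction (`|csmr − p·f|` is exactly zero up to
floating-point rounding).

Rates are piecewise-constant within age groups (a stated convention so
that independent oracles can match the solver exactly), and each group's
prevalence is reported at the group's **start age**. Within a group the
constant-coefficient 2×2 system is advanced with a closed-form matrix
exponential (the eigenvalues are always real because the off-diagonal
entries are non-negative rates), so the solver has no discretisation
error; tests compare it against an independent fine-grid Runge–Kutta
integrator at 200 steps/year and against closed forms (`p = 1 − e^{−ia}`
when `r = f = 0`; the steady state `i/(i+r)` when `f = 0`).

Degenerate inputs: negative rates raise a domain error; if the cohort
fraction underflows to zero (pathological mortality), prevalence is
defined as 0 with a warning.

### Fitting rates to data (`fit_rates`)

Observed inputs are noisy prevalence datapoints per age group and a CSMR
series. The fit minimises a penalised weighted least squares: squared
standardised misfit of modelled prevalence at the datapoints and of
modelled CSMR against the series, plus a squared-second-difference
smoothness penalty on log-rate knots. Parameters are log incidence and
log excess mortality at spline knots (one knot per two age groups,
linearly interpolated in log space) and a single age-constant log
remission rate. Bounds: all rates in [1e−8, 10]/yr; remission capped
(1%/yr default for total diabetes, reflecting the assumption that annual
remission cannot exceed 1%; exactly zero for type 1, which has no cure).
Remission is age-constant rather than a spline because prevalence + CSMR
data identify it only weakly; a per-age remission curve would be pure
prior.

Optimisation is bound-constrained L-BFGS-B with batched finite-difference
gradients. Incidence and remission trade off along a nearly flat valley,
so the point fit first profiles the objective over a short grid of fixed
remission values (warm-starting each refit) before releasing all
parameters; without this the optimiser stalls several percent from the
truth on noiseless data. On noiseless data generated from a smooth truth
inside the model span, fitted incidence and excess mortality land within
5% of truth on interior age groups (asserted in tests).

Uncertainty is a nonparametric bootstrap of the prevalence datapoints
(the CSMR series is perturbed parametrically at its standard error), 100
replicates by default to match the draw count. All replicates are refit
simultaneously by a warm-started projected Adam (150 steps) on the
batched objective — numerically the same criterion as the point fit, two
orders of magnitude faster than sequential refits.

Background mortality `m` is taken as all-cause minus cause-specific
mortality, floored at 1e−6/yr.

### Type 2 by subtraction

Type 2 prevalence is `max(total − type1, 0)` per draw per cell, after
assigning **all** prevalence below age 15 to type 1 (the convention that
diabetes in children is type 1). Draws floored at zero are counted and
reported as a diagnostic.

## Death-type redistribution (`diabem.cod`)

More than half of diabetes deaths in the synthetic death data carry no
type code (configurable; default 55%). The type 2 share among type-coded
deaths is regressed on age-group midpoint, sex and population obesity
prevalence. "Log-linear" is implemented as a linear model of the log
share (predictions clamped to [0, 1]); a logit link is available behind a
flag since the wording admits both readings. Training uses only
country-years passing two filters: more than 50% of diabetes deaths
type-coded, and at least 70% of over-25 type-specific deaths coded type 2
("older than 25" is interpreted as age groups starting at 25 or above).
Rows are weighted by coded death counts; a near-singular design raises an
error carrying the condition number.

Redistribution splits each cell's unspecified deaths by the predicted
share; all deaths under age 15 (coded or not) go to type 1; fractional
deaths are kept (downstream YLLs are real-valued); per-cell totals are
conserved exactly. On the synthetic world with a 50% unspecified
fraction, the recovered global adult type 2 death share is within 2
percentage points of truth.

## Case-definition crosswalk (`diabem.crosswalk`)

Alternate definitions (HbA1c, OGTT, post-prandial glucose) are mapped
onto the reference definition (FPG ≥ 7 mmol/L or medication use) by a
log-ratio estimated from matched pairs by least-trimmed squares, trimming
exactly `⌈0.10·n⌉` pairs chosen to minimise the trimmed sum of squares.
For this intercept-only model the optimal trimmed subset is always a
contiguous window of the sorted log-ratios, so the exact LTS optimum is
found by a sliding-window scan at any `n`; no combinatorial search or
concentration heuristic is needed (tests verify agreement with an
exhaustive subset search). The estimator's breakdown behaviour is tested
directly: scaling a gross outlier tenfold moves the estimate by < 1e−6.

Adjustment divides observed values by the estimated ratio; the ratio's
standard error is added in quadrature on the adjusted scale, so adjusted
standard errors never fall below the sampling ones. Bias covariates
beyond the definition label are out of scope.

Mean-FPG-only reports convert to prevalence as the upper-tail mass above
7 mmol/L under a two-parameter population FPG distribution — lognormal by
default (glucose distributions are right-skewed), normal as an option.
This is a deliberate simplification of ensemble-distribution modelling to
a named two-family choice, recorded in output metadata.

## Burden accounting (`diabem.burden`)

- **YLL** = deaths × standard remaining life expectancy at the
  representative age of the group (midpoint; open-ended top group uses
  start + 2.5 years, since the life table is finer than the age grid).
- **YLD** = Σ over sequelae of prevalence × sequela split × disability
  weight × population, comorbidity-corrected. The four sequelae
  (neuropathy, diabetic foot, lower limb amputation, vision loss due to
  retinopathy) are mutually exclusive splits of prevalent cases;
  co-occurring background ill health combines multiplicatively under
  independence (combined DW = 1 − Π(1 − DW_k)), and the combined
  disability is allocated to each component proportionally to its own
  weight. The correction factor is ≤ 1 whenever background disability is
  positive, so it never inflates YLDs.
- **DALY** = YLL + YLD, draw-wise; additivity survives any aggregation to
  1e−9 relative (asserted).
- **Standard population**: the unweighted mean of age-proportional
  distributions of locations whose total population strictly exceeds
  5 million at the reference year (2019). Age-standardised rates are the
  weight-sum of age-specific rates and always lie within the range of the
  age-specific rates.

Disability weights and sequela splits are synthetic inputs of plausible
magnitude (weights 0.13–0.19; splits summing to 0.32, the uncomplicated
remainder contributing no YLDs); no claim is made that they match any
published weight. The life table is likewise synthetic: remaining life
expectancy declining from ~86 years at birth, floored at 2 years.

## Risk attribution (`diabem.risks`)

Relative-risk curves are piecewise-linear on a stated exposure grid — an
exact, hand-checkable interpolant that preserves the integral structure
of the PAF (spline fitting of risk curves is out of scope; the robust
trimming such fits use is exercised in the crosswalk). Curves are
normalised at the TMREL (interval TMRELs use the uniform average of the
curve over the interval); PAFs are

    PAF = (E[RR(X)] − 1) / E[RR(X)]

with the expectation a probability-weighted sum (categorical) or a
trapezoid integral on the grid (continuous). Negative PAFs are allowed
when observed exposure is protective relative to the TMREL. PAFs are
validated against a counterfactual Monte-Carlo oracle (simulate
individual exposures with incidence ∝ RR, move everyone to the TMREL,
compare case counts) within 3 Monte-Carlo standard errors.

Attributable DALYs are PAF × DALYs draw-wise. Risks combine as
1 − Π(1 − PAF_j), an independence approximation: no mediation matrix is
applied, so the combined figure is not comparable to mediation-adjusted
published aggregates. The registry holds 16 risks; high and low air
temperature attach to both diabetes types, all others to type 2 only.
High body-mass index is continuous with a TMREL interval of 20–25 kg/m²,
and its exposure distribution is rebuilt per stratum from the world's
mean-BMI covariate (normal, sd 4 kg/m²).

## Forecasting (`diabem.forecast`)

Historical prevalence is logit-transformed (clamped to [1e−6, 1−1e−6]
first — zero-prevalence cells exist at young ages) and regressed on a
single covariate with one global slope β₁ and a stratum intercept
α_{l,a,s}: the Socio-demographic Index for type 1, mean BMI for type 2.
The intercept is a random effect by default (REML via a linear mixed
model); an exact within-stratum fixed-effects estimator is available
behind a flag, since the mean structure alone does not dictate the
estimation method. A time-constant covariate makes the slope
unidentifiable and raises an error.

Projections are `expit(β₁·x + α)` on the covariate forecast (covariate
and population forecasts are *inputs*; they are not modelled).
Anchoring: the 2021 difference between estimated and projected
prevalence, in natural rate space, is added to every forecast year and
the result clamped to [0, 1] (clamp events counted); the shifted series
equals the 2021 estimate to 1e−12. Case counts are prevalence ×
population per cell; the total-diabetes forecast is the per-cell sum of
the type 1 and type 2 forecasts. Slope recovery is verified at 30 strata
× 32 years with residual sd 0.05: the median relative error of β₁ over
50 seeded replicates is below 10%.

An annualised rate of change can be derived as ln(ratio)/years; it is
informational only and not asserted against anything.

## Uncertainty and presentation (`diabem.reporting`)

100 draws per cell by default, propagated through every stage;
operations that would change the draw count fail loudly. Draw families
are declared per quantity: normal in natural space, lognormal for
non-negative rates/counts, logit-normal for proportions (no draw
distribution family is canonical; these are fixed and tested choices).
Summaries are the mean plus the 2.5th/97.5th percentiles with linear
interpolation between order statistics. Percentage changes are computed
draw-wise and only then summarised — summary-level arithmetic on rounded
values gives a different number, and a test asserts the difference on a
skewed example. Formatting: counts to three significant figures, rates
and percentages to one decimal, half-away-from-zero rounding.

## The synthetic world (`diabem.world`)

The generator emulates the statistical structure the analysis assumes,
with a known embedded truth:

- **Grid**: 5 locations (flat hierarchy plus a global aggregate; no
  multi-level region structure), 20 five-year age groups (0–100), both
  sexes, years 1990–2021 with covariate/population series through 2050,
  seeded and byte-reproducible.
- **Truth**: type-specific incidence, remission and excess-mortality age
  curves per location-sex-year, with type 1 incidence peaked in
  childhood and linked to SDI, type 2 incidence adult-onset (zero below
  age 15, so all under-15 diabetes is truly type 1) and linked to
  obesity prevalence; true prevalence is the illness-death solution of
  these curves. Total = type 1 + type 2 for incidence, CSMR and
  prevalence.
- **Survey noise**: binomial sampling at the effective sample size
  implied by a target standard error (0.02 default — a mid-sized
  national survey), matching survey microdata structure; additive
  Gaussian noise would allow negative prevalence. Survey
  measurement-error magnitude is not externally calibrated; it is a free
  config parameter. Type 1 datapoints use a much smaller target SE
  (0.0002), reflecting registry/claims-like precision — with a survey-
  scale SE, binomial granularity at ~0.1% prevalence destroys the
  signal.
- **Outliers**: at rate 0.05, a datapoint's truth is multiplied by 0.2
  or 5 before sampling — the gross-contamination regime the 10% trim
  targets.
- **Deaths**: real-valued counts from population × true CSMR, with a
  per-location unspecified-coding fraction centred on 0.55.

What passing tests show — and do not show: recovery works when the data
*are* generated by the assumed model (binomial noise, piecewise-constant
rates, log-linear type split, single-covariate logit trends). Real
surveys have design effects, age-heaping and non-sampling bias; real
death registration has garbage-code reassignment upstream of type
splitting; real risk curves are nonlinear in ways a piecewise-linear
registry entry only approximates. The test-bed validates the *machinery*
(estimators, identities, conservation, uncertainty plumbing), not the
epidemiology of any real population. Headline numbers from the synthetic
world (e.g. ~7% age-standardised prevalence, type 2 share ~99%) are
properties of the generator's defaults, not estimates of the real global
burden.

## Problem sizes and run times

Defaults keep a full run desk-scale: the end-to-end pipeline (5
locations × 20 age groups × 2 sexes, 100 draws, consistency fits at
1990/2000/2010/2021 with bootstrap draws at 1990 and 2021) completes in
roughly two minutes on one CPU; the complete test suite in under ten.
History between fit years is interpolated logit-linearly per stratum
rather than fitted year-by-year — the forecasting regressions only need
a smooth stratum trend, and 4 fit years × 20 strata × 2 causes already
exercise every code path.

## Known limitations

- No hierarchical location cascade, no covariate effects inside the
  consistency fit, no claims-specific corrections, no age-spline
  crosswalks.
- The remission cap is applied per age group (whether the 1% ceiling is
  per-age or global is ambiguous; per-age is the stricter reading).
- Combined PAFs ignore mediation between overlapping risks.
- Bootstrap draws understate posterior uncertainty relative to a full
  Bayesian treatment; they share only the draw-based downstream
  contract.
- The type 1 forecasting slope on SDI is weakly identified in the
  synthetic world (small within-stratum SDI variation against noisy,
  granular type 1 estimates) and can change sign between seeds; the
  type 2 slope on BMI is stable.
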