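# Methods

This note documents the model implemented in `vitdcea`, the defaults it
ships with, the choices made where the published description of this kind
of analysis is genuinely open, and what the tests do and do not establish.

## Decision problem

Two strategies for a defined region (36,413 children under 4; three
skin-tone strata of 17,344 / 14,117 / 4,952): *current practice* and a
programme offering free vitamin D supplements to pregnant women and
children under four, with an administration/promotion budget.  Outcomes are
expected discounted costs (GBP, 2016–17 prices) and QALYs per child
entering the model at birth.  The base-case horizon is 4 years; a scenario
extends to lifetime.

## Parameters and distributions

Every parameter is a `ParamSpec`: point estimate + PSA distribution +
reported SD.  Conventions: beta(a,b) with mean a/(a+b); gamma is
shape–scale; log-normal (a,b) is interpreted as the *natural-scale* mean
and SD moment-matched to the log scale, so the analytic mean equals the
quoted point (an `(μ, σ)`-on-log-scale reading is available via
`log_scale_params`).  Source tables of this kind often quote distribution
parameters that are inconsistent with the quoted SD (e.g. a utility beta
whose analytic SD is 0.068 against a quoted 0.18) or point (the children's
baseline-uptake beta implies 8.8% against a quoted 9.64%).  The registry
deliberately keeps all quoted surfaces — deterministic runs use the point,
the PSA samples the quoted distribution — and
`ParamRegistry.validation_report()` flags every mismatch rather than
refitting silently.  A method-of-moments helper (`fit_from_moments`) exists
for user-supplied parameters; note that refitting a beta to (0.621, 0.18)
gives beta(≈3.89, ≈2.37), *not* the quoted beta(30.64, 18.70) — the quoted
parameters are what the PSA uses by default.

The "SD assumed to be 10% of the reported mean" rule used for uptake
changes and treatment costs is exposed as `assumed_sd()`.

Seeding: one master seed; each parameter samples from a sub-stream keyed by
`(master_seed, sha256(name))`, so adding or removing a parameter never
perturbs another's draws and runs are reproducible across processes.

## Epidemiology

Annual risk = (cases/window)/population.  Defaults use integer case totals
2/29/25 over a 6-year window, which reproduce the quoted per-100,000 rates
(1.92 / 34.23 / 84.14, general 25.63) that rounded per-year counts do not;
window and counts are configuration, not constants.  Multi-year risk uses
independent-year compounding 1 − (1 − p)⁴ (linear 4p available).  The
intervention odds ratio is applied on the odds scale each year.  The
proportion of onsets before 48 months uses the Wilson score interval (it
reproduces the quoted 0.86–0.98 for 54/57; Clopper–Pearson does not — the
exact method remains available via the `method` argument).  One dark-skin
case present in the demographic table (26) is absent from the rate table
(25 over 6 years); the rate-table counts are used for risk estimation.

## Costing

Supplement cost is pro-rata pack price; the 270-day default pregnancy
course reproduces the quoted £3.57 from £0.74/56 days.  The children's
annual cost computes to £9.907 (quoted as £9.90); internals are never
rounded — pounds are rendered at 2 dp (round-half-even) only in the report
layer, which is also why incremental columns are always computed from
unrounded internals.  The payer-coverage policy — whose supplements the
health service is costed for — is configurable: `incremental-uptake` (only
the uptake increase; default), `all-supplemented`, or `universal`.  The
administration budget (default £10,000/year) is spread over the region's
children; an option includes pregnancies in the denominator.  Discounting
defaults to 3.5%/year for both costs and QALYs (the reference-case rate for
UK appraisals), configurable including 0%; cycle-start accrual by default
with a half-cycle correction switch.

## Decision tree engine

Stage 1 runs four annual cycles.  Onset risk applies each year conditional
on no prior onset; the rickets state holds utility 0.621 for the episode
duration (fractional durations blend the boundary year pro rata), truncated
at the horizon in the 4-year base case.  Treatment cost is charged at
onset.  All-cause mortality comes from a life table; none is named for
this analysis, so the bundled table (`life_table_synthetic.csv`) is a
stylised Gompertz-like construction, clearly labelled synthetic, and any
(age, qx) CSV can replace it.  Mortality is independent of rickets state,
so path probabilities factorise; the audit trace records per-cycle
survival, onset and utilities and checks path probabilities sum to one.

Baseline utility uses the quoted quadratic-in-age equation with clipping at
zero.  Taken literally that equation reaches zero near age 61–62, which is
implausible for population norms; it is implemented exactly as quoted
(fidelity first), with a `population_norm` variant (age + age² form,
coefficients 0.9508566, −0.0002587, −0.0000332, +0.0212126) as a
configuration switch for users who want credible old-age utilities.  QALYs
are a 50/50 male/female mixture by default (`male_share` configurable);
clipping is applied per sex before mixing, and decrements applied to the
mixed mean are floored at zero.

Stage 2 (scenario) continues to age 100.  Rickets cases acquire lifelong
complications with probability 0.10; sufferers accrue a 0.05 utility
decrement and an annual management cost for life.  No management cost is
published ("expert estimates" only), so the default £150/year is this
package's own expert-opinion stand-in, marked synthetic in the
configuration; it affects only the scenario and only through the
complication channel.  The deficiency channel (prevalence 0.23, disutility
0.002 from age 67.04, mortality RR 1.05 from age 76.92) applies equally in
both arms — deficiency prevalence is assumed to return to the population
baseline regardless of the programme — so it moves absolute totals, never
increments.  Onset ages are compared against integer cycle ages
(age ≥ onset-age), i.e. the first affected cycle is the first whole year of
age past the threshold.

## Calibration caveat

Absolute published cost/QALY levels (e.g. 4-year QALY totals near 3.334)
cannot be reconciled with the quoted baseline-utility equation under any
standard discount rate, and the original analysis does not state its
discount rate, accrual convention, sex mix or life table.  The engine
therefore exposes all of these as knobs and treats *incremental ratios and
qualitative direction* as the reproducible surface: recomputed ICERs from
the published incremental columns (19,295; 404,074; dominant), and the
pattern dark-dominant / medium near £20,000 / light far above threshold,
which this implementation reproduces across the knob grid (deterministic
medium ICER ≈ £16,300 at defaults).  Absolute per-child totals from this
engine are internally consistent but not comparable one-to-one with the
published table.

## Uncertainty analyses

PSA: independent joint draws (no correlation structure is published; a
rank-correlation hook exists but is not implemented), model evaluated per
draw, default 10,000 samples (no published PSA size).  Summaries report
mean increments, the CEAC at λ = £20,000/£30,000, and the ICER of mean
increments — per-sample ICER means are unstable ratio statistics, and the
implausibly tight published "95% CI" for a mean PSA ICER is not
reproduced; an NMB-based sample interval is reported instead.  Tornado
sweeps evaluate at the 2.5th/97.5th distribution percentiles.  Threshold
search bisects the NMB sign (Brent's method, relative tolerance 1e-6) after
a 9-point monotonicity screen; out-of-bracket crossings return
`below_range`/`above_range` sentinels rather than extrapolated values.

## Synthetic data generator

Emulates the observational structure the estimators assume: Poisson case
counts (binomial by flag) at the configured rates, gamma onset ages
calibrated to mean 21.16 months and P(onset < 48 mo) = 0.95 (the quoted
onset-age SD of 22.42 would over-determine a two-parameter law and is not
enforced), gamma treatment costs at the configured subgroup means/SDs
(the real per-case cost law is unknown beyond "skewed"; gamma is a
choice), 63.16% male, and a six-code tariff fixture with Dirichlet splits
whose only purpose is exercising the line-item I/O.  What passing
round-trip tests show: the estimator pair recovers the configured rates
within exact Poisson intervals in ≥90% of seeds and cost means within
2 SE.  What they do not show: anything about case ascertainment,
biochemical confirmation, or real cost-distribution shape.

## Problem sizes used in checks

The bundled checks run at sizes chosen for tight Monte-Carlo bounds at
interactive speed: 10⁶ draws for sampling-mean convergence, 10⁵ draws for
the linear-model PSA bound (3 standard errors), 10⁴-point grids as the
threshold-search oracle, 200 seeds for generator recovery, and 5,000-draw
PSAs in the reproduction script.

## Known limitations

* Cohort expectation, not microsimulation: no individual heterogeneity
  beyond sex and the modelled states.
* The intervention's effect enters only through the odds ratio on rickets
  incidence; uptake increases affect costs, not effectiveness (consistent
  with the effect estimate capturing pre- and post-natal exposure as
  implemented in the source programme).
* No value-of-information analysis; only two comparators.
* The base-case deficiency and complication channels are off by
  construction; scenario conclusions inherit the expert-opinion inputs'
  uncertainty.
* The life table and complication cost are synthetic stand-ins and are
  labelled as such wherever they appear.
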