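# Default analysis configuration: published point estimates and PSA
# distributions for the free vitamin D supplementation programme model.
# Monetary values are pounds sterling at 2016-17 prices.
master_seed: 1

parameters:
  rickets_utility:
    point: 0.621
    sd: 0.18
    family: beta
    a: 30.64
    b: 18.70
    source: "CHU9D proxy valuation of rickets, UK general-population tariff"
  rickets_duration:
    point: 2.0
    sd: 0.2
    family: gamma
    a: 100.0
    b: 0.02
    source: "expert opinion; SD assumed"
    note: "years in the rickets state; gamma is shape-scale"
  deficiency_disutility:
    point: 0.002
    sd: 0.001
    family: beta
    a: 958479.4
    b: 478281120.8
    source: "proportionate EQ-5D disutility of adult vitamin D deficiency"
  deficiency_disutility_onset_age:
    point: 67.04
    sd: 6.70
    family: normal
    a: 67.04
    b: 6.70
    source: "age at which deficiency-related disutility onsets; SD assumed"
  complication_disutility:
    point: 0.05
    sd: 0.005
    family: beta
    a: 38000.0
    b: 722000.0
    source: "expert opinion (lifelong complications; scenario only)"
  complication_probability:
    point: 0.10
    sd: 0.01
    family: beta
    a: 8999.99
    b: 81000.0
    source: "expert opinion (share of cases with lifelong complications)"
  complication_cost_annual:
    point: 150.0
    family: fixed
    a: 150.0
    source: "synthetic stand-in for an expert-elicited management cost, GBP/year"
  deficiency_prevalence_baseline:
    point: 0.23
    family: fixed
    a: 0.23
    source: "pooled national-survey prevalence of adult vitamin D deficiency"
  rickets_or:
    point: 0.41
    sd: 0.34
    family: lognormal
    a: 0.41
    b: 0.34
    source: "odds ratio for rickets under a regional supplementation programme"
    note: "(a, b) are the natural-scale mean and SD, moment-matched to log scale"
  baseline_supp_woman:
    point: 0.41
    family: beta
    a: 6446.0
    b: 9278.0
    source: "baseline supplement uptake, pregnant women"
  baseline_supp_child:
    point: 0.0964
    family: beta
    a: 4104.0
    b: 42656.0
    source: "baseline supplement uptake, children under 4"
  uptake_increase_woman:
    point: 0.17
    sd: 0.017
    family: beta
    a: 2871.95
    b: 14022.0
    source: "increase in distributed supplements, women; SD assumed 10% of mean"
  uptake_increase_child:
    point: 0.20
    sd: 0.02
    family: beta
    a: 1999.97
    b: 8000.0
    source: "increase in distributed supplements, children; SD assumed 10% of mean"
  mortality_rr:
    point: 1.05
    sd: 0.02
    family: lognormal
    a: 1.05
    b: 0.02
    source: "all-cause mortality RR of vitamin D deficiency in later life"
  mortality_rr_onset_age:
    point: 76.92
    sd: 8.84
    family: normal
    a: 76.92
    b: 8.84
    source: "age from which the deficiency mortality RR applies"

subgroups:
  light:
    census_count: 17344
    cases_total: 2
    window_years: 6
    treatment_cost_mean: 1750.0
    treatment_cost_sd_observed: 48.0
  medium:
    census_count: 14117
    cases_total: 29
    window_years: 6
    treatment_cost_mean: 2385.0
    treatment_cost_sd_observed: 3759.0
  dark:
    census_count: 4952
    cases_total: 25
    window_years: 6
    treatment_cost_mean: 7305.0
    treatment_cost_sd_observed: 16208.0

costing:
  admin_budget_per_year: 10000.0
  discount_rate_costs: 0.035
  price_year: "2016-17"
  pregnancy_supplement_days: 270.0
  coverage_policy: incremental-uptake
  spread_admin_over_pregnancies: false
  target_pregnancies: 0
  child_pack_price: 1.52
  child_days_per_pack: 56.0
  woman_pack_price: 0.74
  woman_days_per_pack: 56.0

model:
  discount_rate_qalys: 0.035
  male_share: 0.5
  half_cycle: false
  max_age: 100
  utility_variant: quadratic   # or population_norm

psa:
  n_samples: 10000
  lambda_grid: [20000.0, 30000.0]

observational:
  onset_before_48mo_k: 54
  onset_before_48mo_n: 57
  onset_mean_months: 21.16
  onset_sd_months: 22.42
  sex_male_prob: 0.6316
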