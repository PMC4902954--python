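# Default parameter set for the five-year early cost-effectiveness model of
# RA diagnostic test strategies.  Every entry carries a provenance tag:
#   source: paper   - value printed in the source study
#   source: fixture - documented stand-in for an unpublished input (the
#                     study's supplementary tables / cohort-derived values);
#                     replace freely, downstream code only reads the value.
# Costs are EUR at the 2014 price level; utilities are EQ-5D index values.

base_criteria:
  value: {sensitivity: 0.62, specificity: 0.77}
  source: paper

prevalence_12m:
  value: 0.54
  source: paper

horizon_years:
  value: 5
  source: paper

cycle_months:
  value: 3
  source: paper

# DAS28 category cuts: remission <= 2.6 < low activity <= 3.2 < moderate/severe
das28_cuts:
  value: [2.6, 3.2]
  source: paper

# Continuous-score bands backing the three categories; the outer edges (0 and
# 6) bound the scores drawn uniformly within a band.
das28_band_edges:
  value: [0.0, 2.6, 3.2, 6.0]
  source: fixture

biologic_uptake_24m:
  value: 0.15
  source: paper

# 24-month clinical-practice uptake of 15 % converted to a 3-month start
# probability under a constant rate: 1 - 0.85^(1/8) ~= 0.02
biologic_cycle_start_prob:
  value: 0.02
  source: paper

# Relative start weights over states 1-2-3, from flare rates
biologic_alloc_weights:
  value: [1.0, 3.0, 6.0]
  source: paper

# "weighted": per-cycle starts distributed over states by the weights among
# ever-eligible patients; "state3_only": starts only from state 3
biologic_start_convention:
  value: weighted
  source: fixture

biologic_annual_cost:
  value: 14000.0
  source: paper

fp_biologic_fraction:
  value: 0.10
  source: paper

# Misdiagnosed (FP) biologic costs charged in year 1 ("first_year") or spread
# over the first background year ("background")
fp_biologic_timing:
  value: first_year
  source: fixture

baseline_utilities:
  value: {TP: 0.60, FP: 0.65, TN: 0.65, FN: 0.60}
  source: paper

first_year_utility_deltas:
  value: {TP: 0.10, FP: 0.05, TN: 0.10, FN: -0.05}
  source: paper

background_utility:
  value: 0.75
  source: paper

dip_prone_fraction:
  value: 0.25
  source: paper

dip_threshold:
  value: 0.50
  source: paper

# DAS28 improvement at 12 months for patients detected only by the new
# strategy (TP under the new test, FN under the criteria)
das28_benefit:
  value: 0.2
  source: paper

discount_costs:
  value: 0.04
  source: paper

discount_effects:
  value: 0.015
  source: paper

wtp:
  value: 20000.0
  source: paper

# "per_test": headroom per administered test (divide by the tested
# fraction); "per_cohort": headroom per cohort patient
headroom_convention:
  value: per_test
  source: fixture

# First-year visits + diagnostic workup under the criteria pathway
current_workup_cost:
  value: 1593.0
  source: paper

# Visit component retained when the new test replaces all blood tests and
# radiographs of the criteria workup
replacement_visit_cost:
  value: 850.0
  source: fixture

# Year-1 RA-related treatment costs by classification, on top of the workup:
# TP receive a full year of tight-control synthetic DMARD care; FP receive
# care until the misdiagnosis is dropped; FN receive symptomatic care only.
# FP biologic costs are added separately via fp_biologic_fraction.
first_year_treatment_costs:
  value: {TP: 2400.0, FP: 1100.0, TN: 0.0, FN: 450.0}
  source: fixture

# DAS28-state occupancy at 12 months for patients entering the
# state-transition model.  FN (untreated) patients carry more mass in the
# moderate/severe state than treated TP patients.
entry_state_distributions:
  value:
    TP: [0.45, 0.30, 0.25]
    FN: [0.20, 0.25, 0.55]
  source: fixture

# 3-month transition matrices over states (remission, low, moderate/severe);
# rows are stochastically ordered (worse states transition worse) and the
# biologic stratum has better control.
transition_matrix_nonbio:
  value:
    - [0.80, 0.15, 0.05]
    - [0.30, 0.45, 0.25]
    - [0.10, 0.25, 0.65]
  source: fixture

transition_matrix_bio:
  value:
    - [0.85, 0.12, 0.03]
    - [0.40, 0.45, 0.15]
    - [0.20, 0.30, 0.50]
  source: fixture

# Per 3-month-cycle costs by state (EUR): rheumatology care, monitoring and
# synthetic DMARDs (direct), and absence from paid work (productivity)
state_costs_direct:
  value: [200.0, 500.0, 1100.0]
  source: fixture

state_costs_productivity:
  value: [250.0, 700.0, 1600.0]
  source: fixture

# Cycle utilities by biologic stratum and utility-mixture membership; the
# dip-prone mixture sits partly below the 0.50 dip threshold.
state_utilities:
  value:
    non_biologic:
      typical: [0.83, 0.74, 0.62]
      dip_prone: [0.70, 0.58, 0.42]
    biologic:
      typical: [0.80, 0.71, 0.58]
      dip_prone: [0.66, 0.54, 0.40]
  source: fixture

# PSA spread conventions: beta/Dirichlet concentration (alpha+beta) and
# gamma coefficient of variation
psa_beta_concentration:
  value: 100.0
  source: fixture

psa_gamma_cv:
  value: 0.15
  source: fixture
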