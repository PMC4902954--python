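# Methods

## Model structure and assumptions

The model evaluates diagnostic strategies for suspected rheumatoid
arthritis (RA) over a five-year horizon from a societal perspective. It
has two phases.

**First year.** A decision tree classifies each of the 552 cohort
patients as TP, FP, TN or FN at 12 months. Classification is an
expectation over the strategy's combined sensitivity/specificity applied
to the cohort's RA and non-RA totals (cells rounded half-up, complements
taken so totals are conserved), or — in patient mode — per-patient
Bernoulli test results. The tree's interim 6-month chance node is
collapsed into the 12-month classification: outcomes are defined only at
12 months, and within-year treatment switching is absorbed into the
year-1 cost parameters. Year-1 utilities change linearly, so the QALY is
the trapezoidal integral `baseline + delta/2`; year-1 flows are
undiscounted (discounting starts with the second model year, the Dutch
differential-discounting convention of 4 %/yr for costs and 1.5 %/yr for
effects applied as `(1+r)^(−t)` at cycle-start times).

**Years 2–5.** RA patients (TP and FN — classification does not change
who has RA, only when treatment starts) enter an individual-level
state-transition model in 3-month cycles over three DAS28 states
(≤ 2.6 / ≤ 3.2 / > 3.2). Eligibility for biologic DMARDs is sticky: a
patient in the moderate/severe state at 12 months or any later cycle
stays eligible. Among eligible patients not yet on a biologic, starts
occur with overall per-cycle probability 2 % — the registry-observed 15 %
uptake at 24 months converted under a constant rate,
`1 − 0.85^(1/8) ≈ 0.02` — distributed over the current states
proportionally to 1–3–6 weights and renormalised each cycle so the
overall 2 % is preserved whatever the occupancy. This reading reconciles
the eligibility rule (ever above 3.2) with the stated distribution of
starts over all three states; the stricter alternative (starts only from
state 3) is available via `biologic_start_convention: state3_only`. Once
started, patients never discontinue, and switching between agents is
cost-neutral at €14,000/year, so it is not modelled as an event. There is
no half-cycle correction and no death state (five-year RA mortality is
1–2 % and equal across strategies). TN/FP patients follow a background
track: constant utility 0.75, no RA-related costs; the biologic cost of
10 % of FP patients is charged in year 1 by default
(`fp_biologic_timing: background` spreads it over the first background
year instead).

**Early-detection benefit.** Patients positive under the new strategy but
negative under the criteria enter the transition model from the untreated
(FN) entry distribution improved by 0.2 DAS28. Entry states are backed by
a continuous DAS28 drawn uniformly within each state band (band edges
0–2.6–3.2–6.0), so the benefit moves exactly the mass within 0.2 of a
cut; with the benefit at 0 the shift is the identity.

## Reference cohort derivation

The original cohort (552 patients, strata 243/263/46, 54 % RA at 12
months) is not deposited. The integer RA/non-RA split per stratum is
recovered by exhaustive search: total RA constrained to within one
patient of 0.54 × 552, each candidate scored by total absolute deviation
between forward-predicted counts and the twenty published cells (sixteen
reclassification counts, four confusion counts). Two splits tie on the
counts — (185, 97, 17) and (185, 98, 16) RA in high/intermediate/low —
so the published intermediate-only combined accuracies, which pin down
the intermediate stratum's shares, break the tie lexicographically. The
winner, high 185/58, intermediate 97/166, low 17/29, reproduces the
current-strategy confusion row and all intermediate reclassification
rows exactly, and the low-risk rows within one patient (the published
low-risk MRI cell itself disagrees with its printed percentage by one).

## Parameters

All inputs live in one annotated file
(`src/earlycea/data/default_parameters.yaml`); each entry is tagged
`source: paper` (printed value) or `source: fixture`. The fixture values
replace the study's unpublished supplementary inputs and were chosen once
on clinical plausibility, not calibrated to outputs:

- **Entry distributions at 12 months** — TP (0.45, 0.30, 0.25), FN
  (0.20, 0.25, 0.55): treated patients concentrate in remission, untreated
  patients in moderate/severe disease.
- **Transition matrices** (quarterly) — diagonally dominant,
  stochastically ordered rows (a worse current state never implies a
  better next-state distribution, which also makes the early-detection
  benefit propagate monotonically under common random numbers); the
  biologic stratum has better control.
- **State costs per cycle** — direct medical €200/€500/€1,100 and
  productivity €250/€700/€1,600, increasing with disease activity;
  productivity losses dominate in the severe state, as is typical for RA
  of working age.
- **Utilities** — by state, biologic stratum and mixture membership. A
  quarter of patients are "dip-prone" (their utility falls below 0.50 at
  least once over follow-up); their severe-state values sit below the
  0.50 threshold. Non-biologic users have slightly higher utilities,
  matching the trial observation.
- **Year-1 treatment costs** — TP €2,400 (a year of tight-control
  synthetic DMARD care), FP €1,100, FN €450, TN €0.

Because these are stand-ins, the package reproduces the published
*classification* layer exactly but not the published cost/QALY/ICER/
headroom magnitudes; tests therefore assert structural properties of the
economic layer (headroom self-consistency against the threshold, ICER
scale invariance, monotonicity in specificity and in the DAS28 benefit)
rather than published euro values.

## Synthetic data: what it does and does not emulate

The generated populations reproduce the printed marginal structure —
cohort size and strata, RA prevalence, confusion counts, the 25 %
dip-prone fraction, uptake reaching ~15 % by 24 months — with exact
label counts by construction (rank-deterministic assignment) and all
randomness from one seeded generator. They do not emulate covariate
structure (age, sex, serology), correlation between the criteria and new
tests beyond conditional independence, or secular treatment drift.
Passing tests therefore validate the model mechanics and the published
classification arithmetic, not the economic magnitudes that would follow
from the study's real inputs.

## Probabilistic sensitivity analysis

Beta laws for scalar probabilities and utilities (mean preserved,
concentration κ = 100 by default), Dirichlet for entry distributions and
matrix rows (α = κ·p), gamma for costs (CV 0.15), utilities of the
dip-prone mixture on a scaled support reaching the EQ-5D floor (−0.59).
Test sensitivity, specificity and unit cost are held fixed — the point of
the early assessment is to evaluate hypothetical tests at nominal
operating points; their influence is explored in the one-way analysis
instead (defaults: Se and Sp 0.50–1.00, cost 0–2×, DAS28 benefit 0–0.6,
FP-biologic fraction 0–20 %). Common random numbers apply within and
across PSA draws, so the draw cloud isolates parameter uncertainty;
setting the spread parameters to (∞, 0) reproduces the base case exactly.

## Numerical conventions

- Half-up rounding for expected counts, applied per cell; complements
  keep totals conserved (published rows themselves are independently
  rounded and can be off by one).
- Combined accuracies are displayed at 2 dp but propagated unrounded.
- Headroom is quoted per administered test (division by the tested
  fraction τ); the per-cohort-patient convention is available via
  `headroom_convention` since published intermediate-strategy headrooms
  are not internally consistent about τ.
- ICER of (0, 0) is 0; a cost difference with exactly zero QALY
  difference raises an explicit undefined-ratio error rather than
  returning ±∞.
- Simulation sizes: the shipped cohort (552 patients; 299 entrants, 16
  cycles) runs in ~8 ms, so the default 1,000-draw PSA takes seconds;
  property tests use 10,000-patient populations where Monte-Carlo error
  must be small.

## Known limitations

No radiographic-damage or HAQ progression, no treatment sequences beyond
the biologic flag, no adverse events, no mortality, no correlation
between diagnostic tests. The fixture transition matrices mix within a
few quarters, so entry-state advantages (and hence the QALY gain from
early detection) decay faster than they plausibly would in a cohort with
more persistent disease activity; absolute ICERs under the defaults
should be read as illustrative, directions and comparative statics as
the tested substance.
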