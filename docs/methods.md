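# Methods

## Model structure

`obesim` implements a deterministic, discrete-time (annual cycle) Markov
closed-cohort model. The cohort is a probability vector over 19
mutually exclusive health states:

- 15 cancer-free alive states: {NGT, prediabetes, T2D} ×
  {event-free, acute ACS year, post-ACS, acute stroke year, post-stroke};
- 3 cancer states (colorectal, postmenopausal endometrial,
  postmenopausal breast). Glycemic and cardiovascular detail is not
  tracked inside cancer: cancer mortality is a flat annual probability
  and no further transitions are modelled from cancer, so the extra
  detail would be inert. Collapsing it keeps the state space small and
  the reporting families exact;
- 1 absorbing dead state.

Collapsed over the cancer branch these aggregate to 18 obesity-related
state families plus death (`state_family`). Knee replacement and sleep
apnea are overlay attributes, not states: knee replacement is a tallied
event that can occur from any alive state; sleep apnea is a prevalent
cohort share with no effect on mortality or transitions.

A severity partial order governs admissible transitions: glycemic status
is non-decreasing (NGT < prediabetes < T2D), cardiovascular history
never returns to event-free, the acute year states are one-cycle tunnels
into their post-event states, cancer type is permanent, and death is
absorbing. Self-transitions are always order-respecting (staying put is
not a regression). Recurrent events from post-ACS may be an ACS or a
stroke; recurrent events from post-stroke all route to the stroke-year
state, because passing post-stroke mass through the ACS tunnel would
erase its stroke history. `validate_matrix` reports row-sum deviations
(tolerance 1e-9), negative entries, and any positive probability on a
forbidden transition.

## Transition probabilities

Risk equations are pluggable `RiskModel` objects returning a cumulative
K-year risk from the cohort risk-factor vector. Two coefficient-file
families are supported (logistic, and Cox-style baseline-survival), so
published coefficient sets can be loaded without code changes; a
documented toy logistic parameterisation ships for tests and examples.
Its coefficients were chosen once for realistic magnitudes in a
middle-aged UK-style cohort (≈0.7% 10-year T2D risk at BMI 22.5 under
NGT, rising steeply with BMI and glycemia; mid-single-digit 10-year CVD
risk, diabetic > normoglycemic and recurrent > first at roughly a
doubling each), and the validation workflow relies only on their
monotonicity in BMI and in the glycemic marker.

Numerical conventions:

- **Annualisation.** Cumulative K-year risks map to per-cycle
  probabilities by `p = 1 − (1 − R)^{1/K}`; the compounding inverse
  round-trips to better than 1e-9 over [0, 1), and `R = 1` stays 1.
- **Hazard-ratio application.** `p' = 1 − (1 − p)^{HR}`
  (complementary-log / rate scale) rather than `p·HR`: identity at
  HR = 1, bounded in [0, 1] for any HR > 0, and within 1e-4 of naive
  multiplication at the annual probabilities involved.
- **Competing risks.** Within a cycle, survivor mass is distributed by
  multiplying independent attribute transitions (glycemic progression ×
  CV event × cancer onset on the no-CV-event branch), so every row sums
  to exactly 1; marginal event probabilities are rescaled only in the
  (unreachable at realistic inputs) case that they exceed 1. Cancer
  onset is only modelled from CV event-free states.
- **ACS vs stroke split.** Composite first/recurrent CVD risk is
  partitioned by a configurable ACS share, default 3.4/7.8 ≈ 0.436 — the
  observed reference-group split of UA/MI vs stroke/TIA rates.
- **Glycemic markers.** The prediabetes stratum is evaluated with HbA1c
  forced to 42 mmol/mol, used as printed as 6.0% (the exact IFCC
  conversion differs slightly; the printed equivalence is kept). The
  NGT stratum uses a configurable mid-normal 5.4%, because the cohort
  HbA1c field describes the diabetic stratum. Prediabetic cohorts use
  the NGT equation for first CV events and the T2D equation for
  recurrent CV events.

## Mortality

Background mortality is an age/sex life table of annual probabilities;
mixed-sex cohorts mix the two columns linearly by the (static) female
share. Event-year and post-event adjustments: MI and unstable angina
30.00% (F) / 32.00% (M) in the event year, then RR 1.30; stroke 24.70% /
17.10%, then RR 2.00; knee replacement 0.30%; cancer onset-year
fatalities 30.11% (colorectal), 10.54% (endometrial), 4.08% (breast),
then a flat 4.31% annually. Adjusted mortality never falls below
background. Where several adjustments could stack the maximum is taken
(configurable to multiplicative RRs); with this state space the case
never arises, since cancer states carry no CV history.

Timing: acute CV case fatality is faced while occupying the one-year
tunnel state (survivors then exit to post-event states), so fatality for
events in the final horizon year falls just outside the horizon — a
negligible truncation over 10 years at these event probabilities.
Cancer onset fatality is instead applied to the incident flux at entry,
because cancer states are not tunnels. The knee-replacement 0.30%
fatality is available through `adjusted_mortality` but not routed into
the cohort engine's death mass by default (incidence × 0.003 is far
below the 0.1/1000 PY reporting precision).

A synthetic Gompertz life-table generator (`h(x) = a·e^{bx}`, defaults
a = 1.6e-5 / b = 0.105 for women, 2.6e-5 / 0.100 for men, ages 0–105)
stands in for national life tables in tests and examples; its discrete
qx reproduce the closed-form survivor function to rounding error, and
ages beyond the table carry the last qx forward.

## Risk-factor dynamics

Fields are static (height, smoking share, triglycerides, lipid-lowering
share, menopause age, female share) or dynamic (age, BMI, SBP, total and
HDL cholesterol, HbA1c and diabetes duration in the diabetic stratum,
antihypertensive share). Treatment effects are deltas from baseline
(BMI as a percentage, others absolute); after treatment stops the deltas
decay linearly to zero over the catch-up period (a step rebound is
available), after which natural drift applies (BMI increase until a stop
age; HbA1c progression). The validation mode freezes everything except
age and durations. The female share is held static over the horizon
even though sex-specific mortality would slowly shift it; with the
10-year validation horizon the induced error is below reporting
precision, and sex-split survival reweighting is a known limitation.

## External validation workflow

Each of the five BMI groups (reference 18.5–24.9 up to 40–44.9 kg/m²) is
simulated for 10 years with a cohort of 100 and frozen BMI, using the
reference group's baseline characteristics with only the group mean BMI
swapped in (22.5, 27.3, 32.1, 37.0, 42.3). The base analysis uses the
reference group's glycemic split (95.3/2.0/2.7% NGT/prediabetes/T2D);
the prediabetes-adjusted scenario uses the survey split 71.4/25.9/2.7%
(T2D prevalence unchanged). Menopause age, absent from the baseline
table, defaults to 51 years.

Events are converted to rates per 1000 patient-years by dividing
cumulative events by person-years, where person-years are the alive mass
summed over cycle ends (undiscounted life expectancy truncated at the
horizon; no half-cycle correction — an optional refinement the base
engine deliberately omits). Observed comparator rates are Cox-adjusted:
reference-group crude rate × BMI-group hazard ratio, reported to one
decimal (half-up).

Concordance is a zero-intercept OLS fit of predicted (Y) on observed
(X): `slope = Σxy/Σx²`. The R² convention —
`1 − Σ(y − bx)²/Σ(y − ȳ)²`, with the total sum of squares about the mean
of the *predicted* values — was selected by brute-force recovery of the
published statistics table from the published rate vectors: it is the
only candidate (vs centering on observed, or uncentered) that reproduces
the printed values, including the strongly negative mortality R².
Slopes and R² are reported to three decimals, rates to one (half-up).
Two published figures are not recoverable from the one-decimal printed
inputs: the mortality base-case slope/R² evaluate to 0.444/−26.839
against printed 0.445/−26.840 (the R² sits 7e-7 below a rounding tie),
and one stroke-row cell rounds to 4.0 against printed 4.1, while the
cross-check that unrounded UA/MI + stroke rates sum to the printed
CV-total row succeeds in all groups; the corresponding tests assert the
printed values and document the discrepancy rather than widening the
check.

## Synthetic data and what passing tests show

The toy risk models and Gompertz life table emulate the *shape* of the
inputs (monotone risk gradients, plausible magnitudes, realistic age
structure of mortality), not any published parameterisation; predictions
built on them are therefore checked for structural properties
(BMI-monotone T2D rates, strictly higher rates under the
prediabetes-adjusted scenario, mass conservation, monotone death mass,
life-table and matrix-power oracles) rather than against the published
predicted rows, which depend on unpublished coefficient sets and 2019
national life tables. Passing tests show the engine, the calculus and
the statistics are correct and that the prediabetes mechanism behaves as
designed; they do not certify predictive accuracy on real cohorts.
Baseline annual rates for the cancer and knee-replacement overlays are
order-of-magnitude placeholders and must be configured from literature
for substantive use.

## Degenerate inputs and tie-breaks

Occupancy construction rejects negative mass and totals off 1 by more
than 1e-6; stepping validates matrices at 1e-9 unless disabled. BMI
outside all hazard-ratio strata clamps to the nearest stratum with a
warning. Postmenopausal cancer probabilities are 0 below menopause age
and weighted by the female share otherwise. Zero person-years,
degenerate concordance inputs (length < 2, all-zero observed, constant
predictions), unknown strata/slots/triggers, and non-existent configured
paths all raise with the offending name. Reported rounding is decimal
half-up throughout, matching the tables' convention.
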