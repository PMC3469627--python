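# Methods

## Model structure

`copdsim` is a deterministic stock-and-flow (system-dynamics) model.  All
stocks are person counts indexed by sex × age band × smoking status
(2 × 4 × 3 = 24 subgroups) and, within each subgroup, by disease/diagnosis
compartment: `tn`, `fp`, `untested` (no COPD), `mild_tp`, `mild_fn`,
`mild_ud`, `moderate`, `severe`.  Time advances by explicit Euler steps of
Δt = 0.25 years (configurable; any Δt that divides one year) from the start
of 2011 to the end of 2035.

Within a step the operation order is fixed: (1) event tally and economic
accrual on the start-of-step stocks, (2) COPD deaths, (3) background
deaths, (4) stage progression, (5) demographic flows (aging, smoking
transitions, migration, entry), (6) mild-incidence top-up.  At Δt = 0.25
the ordering effects are negligible, but fixing them makes every run
bit-reproducible.

Key structural assumptions:

* **Constant subgroup mild prevalence.**  Mild incidence is defined as the
  amount that restores each subgroup's mild prevalence to its published
  value after demography, progression and death flows — incidence is
  therefore proportional to subgroup growth plus mild outflows.  Moderate
  and severe stocks are dynamic, fed only by progression.  A subgroup can
  transiently overshoot its target (smoking cessation moves mild cases
  from a 24.4 % prevalence subgroup into an 8.2 % one); incidence is then
  floored at zero and the overshoot is absorbed within subsequent steps —
  year-boundary prevalences deviate from target by < 1e-12 in the base
  case.
* **Diagnosis.**  The symptom → spirometry cascade is applied to the 2011
  stocks and to each incident mild cohort.  There is no re-testing over
  time; UD/FN patients surface as diagnosed only by progressing.  False
  positives persist (and pay mild maintenance) until death — the inputs
  provide no un-labelling mechanism.  Symptom status is a static
  population fraction, not a dynamic state (only prevalences are
  published, no onset/remission rates).
* **Mortality.**  Background mortality depends on sex, age and smoking
  status only (the published table repeats identical values across disease
  stages).  All COPD-attributable deaths ride on major exacerbations at
  0.046 deaths per major episode, so stage and smoking affect COPD
  mortality only through exacerbation frequency.  In the calibrated base
  case this yields ~10.9K COPD deaths in 2011, matching the ~10,000/year
  national estimate.
* **Aging** is a continuous band-to-band transfer at 1/(band width) =
  0.1/year, the standard compartmental approximation of cohort aging; the
  70+ band absorbs.

## Economics

Costs (2011 CAD) separate maintenance (per patient-year, accrued only by
diagnosed-as-COPD stocks: TP, FP at the mild rate, moderate, severe) from
episode costs (per exacerbation, accrued by every patient including UD/FN).
The identity `maintenance + rate × (minor share × minor cost + major share
× major cost)` reproduces the published per-patient totals from the
primitive unit costs; the printed cells carry a $1 rounding artifact in
three of six positions (they were evidently computed from unrounded
primitives), so the identity is checked to ±$1.  The published indirect
cost shares of total (~20/33/45 % by stage) emerge from the per-unit
inputs and are asserted as a consistency check, not used as an input.

QALY losses have three components:

* **chronic**: stocks × max(0, reference EQ-5D(age) − stage utility) per
  year.  The decrement is clamped at zero because the 70+ reference (0.79)
  sits below the mild chronic utility (0.81); COPD is not allowed to
  improve utility.
* **exacerbation**: episodes × (chronic − episode utility) × episode
  duration.  Durations are not published; defaults are 14 days (minor) and
  30 days (major), typical for COPD economic models, exposed in the
  parameter file.
* **death**: each COPD death loses the reference-utility stream from death
  to the end of the horizon (no post-horizon extrapolation), with the
  decedent's counterfactual self aged forward along the bands by a
  backward recursion over calendar years; deaths are treated as occurring
  mid-year on average.  The reference utility (not the pre-death COPD
  utility) is used, consistent with measuring losses against the
  general-population area under the curve.

Costs and QALYs discount at 3 %/year to 2011 with integer-year exponents
(an amount accrued in 2035 is multiplied by 1.03⁻²⁴ — this reproduces the
published 7.33B → 3.61B identity).  Net monetary benefit uses a
willingness to pay of $50,000/QALY.

## Synthetic demography and calibration

The official population projections behind the original analysis are not
available, so the demography module emulates them.  Chosen once, a priori,
from public Canadian patterns: the 2011 band shares of the 40+ population
(30.3/29.1/21.2/19.4 %), male fractions per band (50/50/48/42 %), a
smoking mix by sex and age centred near current/previous/never ≈
20/30/50 % and shifting toward previous/never with age, cessation 2 %/yr,
and in-model initiation 0.2 %/yr (never → current, 40–49 band only).

Three scalars are then solved deterministically against the published
anchors: the entry rate into the 40–49 band and the uniform net-migration
rate against the 2035 anchors (40+ population 24M, 70+ population 8M), and
a current↔never smoking-mix shift against the 3.45M baseline COPD count
implied by the stage distributions.  The calibrated solution (entry ≈
513K persons/yr, migration ≈ +0.74 %/yr, mix shift ≈ +4 % on the current
share) reproduces all four anchors to < 1e-10 relative and yields 2011
aggregate mild prevalences (12.9 % men, 10.5 % women) close to the
published 12.7 %/10.0 %.

What the synthetic demography does *not* emulate: cohort-specific birth
waves entering the 40–49 band (entry is constant in time), age-structured
migration, trends in smoking behaviour, or provincial heterogeneity.
Passing tests therefore demonstrate the model mechanics and the published
parameter set under a plausible demographic background — not a forecast
fit to the real projection series.

## Interventions

All three interventions are zero-cost multiplicative rate reductions with
full effect from 2011 (no uptake ramp), mirroring the constant
annual-rate-reduction scenarios they emulate.  Intervention II scales both
progression hazards; III scales all three stage exacerbation rates.  For
intervention I (a predisposition screen for people who have just started
smoking), the target flow is smoking initiation, which mostly happens
before age 40: the model therefore treats the current-smoker share of the
cohort entering the 40–49 band as initiation-attributable and scales it by
(1 − e), along with the small in-model never→current rate.  This is the
design choice that lets a screen of incident smokers have any visible
25-year effect in a 40+ model; combined with the no-lag assumption it
tends to *overstate* the intervention's quarter-century payoff, since in
reality today's deterred 20-year-old smokers would not have reached the
modelled ages within the horizon.

## Sensitivity analysis

The tornado perturbs one parameter at a time by ±25 % (a convention — the
source ranges are not published) and ranks spans of cumulative discounted
cost.  "Population growth" is implemented as a common multiplier on the
growth drivers (entry and net migration); "relative risk of COPD in
previous/current smokers" scales those groups' COPD stage prevalences with
the no-COPD share renormalized.  Only the ordering is asserted anywhere;
bar magnitudes are model-specific.

## Numerical choices

* Explicit Euler, Δt = 0.25 y; any single-step outflow exceeding its stock
  raises an error instructing a smaller Δt rather than clipping.
* Published stage-distribution rows sum to 99.9–100.1 % as printed; they
  are stored verbatim and renormalized by their row sum for simulation.
* Calibration uses `scipy.optimize.brentq` (mix shift, 1-D) and
  `least_squares` (entry/migration, 2-D, bounded) on relative residuals;
  anchors violated by more than 2 % after the solve raise a
  `CalibrationError` naming the anchor.
* The model contains no randomness; repeated runs are bit-identical.

## Known limitations

* Two published headline figures are unreachable from the published inputs
  under the stated mechanisms, and the corresponding checks are left
  failing rather than re-tuned.  (1) Aggregate male mild prevalence is
  printed as rising to 18.5 %, above the 17 % maximum subgroup mild
  prevalence — impossible while subgroup prevalences are constant, which
  is the stated mechanism and a structural invariant here; the model gives
  ~12.7 %, and the same gap propagates to the 2035 total COPD count
  (4.94M vs 5.83M printed).  (2) Rebuilding total QALYs lost from the
  published stocks, deaths and utilities under reference-minus-stage
  accounting gives ≈ 12M undiscounted, not the printed 19.0M; this model
  computes 11.7M undiscounted / 7.9M discounted (vs 12.9M printed).
* The severe stock accumulates more strongly here than in the source
  projection (severe prevalence reaching ~5 % vs a printed 2.2 % in men by
  2035), because severe patients face only background plus
  exacerbation-linked mortality; the cost ledger is correspondingly more
  sensitive to progression rates than the source ranking suggests.
* Moderate and severe COPD are assumed fully diagnosed; undiagnosed severe
  disease in reality makes these cost estimates conservative.
* One-way sensitivity only; probabilistic sensitivity analysis is out of
  scope, as are sub-40 cohorts, GOLD III/IV separation, asthma feed-in and
  currency conversion.
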