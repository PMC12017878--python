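# Methods

This note documents the models behind `oncodelay`, the assumptions baked
into their defaults, and the design choices made where more than one
reasonable convention exists.

## Delay categories and conventions

Diagnostic delay — days from symptom recognition to definitive diagnosis —
is analysed in six clinical bands with half-open day ranges
[0,14), [14,30), [30,60), [60,180), [180,365), [365,730).  Conversions are
fixed at 1 month = 30 days and 1 year = 365 days, which keeps the category
boundaries integer-clean.  The open-ended "one year or more" band is
truncated at two years for sampling, the plausible maximum within a
multi-year observation window.  Each category has a representative
evaluation day {0, 30, 60, 180, 270, 360} — whole-month anchor days used
when a per-category point value of a continuous curve is needed; the
reference category evaluates at day 0.  The bands counted as *high risk*
are those beyond two months.

## Synthetic cohort generator

The generator (`synth_cohort`) emulates the statistical structure the
analysis assumes, not any real patient population:

* **Delay**: the category is multinomial with default probabilities
  (45, 84, 40, 241, 60, 169)/639 — the observed symptomatic-cohort
  distribution — and the day is uniform within the category's range.
* **Subtype**: a three-class molecular mix, default HR+ 0.60 / HER2+ 0.25 /
  triple-negative 0.15.  Only receptor *marginals* are reported for the
  reference cohort (75.5% ER+, 68.1% HER2−), not the joint classes, so the
  joint default is a choice consistent with those marginals and with the
  usual clinical ordering; it is configurable.  Receptor flags are drawn
  consistently with the class definitions (triple-negative ⇔ all three
  negative; HER2+ ⇔ HER2 amplified; HR+ ⇔ ER or PR positive, HER2−).
* **Baseline stage**: I/II/III with default probabilities 0.25/0.55/0.20,
  chosen so that after migration the stage-at-diagnosis mix is dominated
  by stage II, as in the reference cohort.
* **Stage migration**: a Bernoulli event with probability given by the
  subtype's migration curve at the patient's delay; on migration the stage
  advances by exactly one level, because the migration curves parameterise
  single-step transitions only.  This makes "no downstaging" a structural
  invariant.
* **Mediators**: the probability of needing treatment beyond surgery
  scales the baseline odds (default base probability 0.45) by the
  per-category intensity odds multipliers (1.0, 1.3, 1.7, 2.4, 3.1, 3.8);
  a second, similarly scaled split allocates multimodality treatment.
  Complication probability is 0.10 + 0.05 × intensity level, giving a
  marginal near the observed 15% complication rate.
* **Survival**: exponential with monthly rate 0.021 × HR(category), where
  the hazard-ratio gradient is (1.00, 1.18, 1.27, 1.54, 1.92, 2.35), with
  administrative censoring at the 120-month horizon.  The exponential
  baseline matches the constant monthly rates of the Markov model; no
  particular baseline shape is claimed for real data — the Cox estimator
  being tested is baseline-free.
* **System intervals**: referral / pathology / treatment-planning waits are
  gamma with means 23.2 / 14.7 / 18.5 days (total 56.4) and shape 4 by
  default; shape `None` degenerates to the exact means.  Shape 4 gives a
  coefficient of variation of 0.5, a realistic dispersion for
  administrative waiting times.

Passing tests on these cohorts demonstrates estimator correctness under
the generating assumptions (proportional hazards, single-step migration,
linear mediation paths).  Real cohorts violate all of these to some
degree — non-proportional hazards, recall error in symptom dates,
informative censoring, confounded mediators — and nothing here speaks to
those violations.

A separate calibrated generator, `generate_mediation_cohort`, produces
(exposure, three binary mediators, continuous outcome) tables whose linear
path products a_k·b_k carry chosen shares of the total effect (default
67.3 / 18.9 / 7.4% with 6.4% direct, total ln 2.35 on the log-hazard
scale).  Exposure→mediator slopes (0.5, 0.4, 0.3 over a unit exposure) are
set to keep Bernoulli means inside (0, 1); the outcome noise SD of 0.5 is
of the same order as the total effect.

## Stage-migration curves, thresholds and NNT

Cumulative migration probability is anchored at 1/3/6/12 months per group
(three stage transitions, three molecular classes) and pinned to (0, 0):
zero delay cannot have caused migration.  Between anchors the default is
piecewise-linear interpolation in days, with constant extrapolation past
the last anchor; a geometric alternative
p(d) = 1 − (1 − p₁ₘₒ)^(d/30) is available behind a flag.  Linear
interpolation exactly reproduces the published nine-month grid cells for
two of the three stage rows (e.g. Stage III→IV (12.1 + 24.3)/2 = 18.2%),
which is why it is the default.

The critical threshold is found by a 1-day-resolution scan, reading
"exceeds 10%" as ≥ 0.10 at integer days.  The published thresholds
(38/52/85 days by subtype, 56/68/73 by stage) are **not** reproducible
from the published anchors under either scheme — linear interpolation of
the triple-negative anchors gives 57 days and the geometric model 59 —
so they are carried as labelled reference constants and always reported
alongside the computed values, never substituted for them.  A second
published table prints yet another stage-level threshold set (78/92/115
days), which linear interpolation does reproduce for Stage I→II (78);
the discrepancy between the two published sets is left as-is.

NNT is ⌈1/ARR⌉ with the absolute risk reduction taken as the three-month
migration probability (an expedited pathway replacing a typical
three-month work-up).  This reproduces the published NNTs for Stage I→II
(9), Stage II→III (13) and HR+ (16) but not Stage III→IV (published 14,
computed 18); the published ARR definition is unknown, so again both are
reported.

## Markov cohort model

Five states, monthly cycles, 120-cycle (10-year) horizon.  Permitted
transitions and overall monthly probabilities: Symptomatic-Undiagnosed →
Diagnosed-Untreated 0.302; Diagnosed-Untreated → Treatment-Initiated
0.424; Treatment-Initiated → Progressive-Disease 0.103 and → Death 0.021;
Progressive-Disease → Death 0.085; Death absorbing.  Stratified values
(by symptom type, delay interval, stage, subtype, treatment type)
override the overall value only where listed; when a query stratum
supplies several applicable keys for one edge, a fixed priority order
(delay interval first) resolves the tie deterministically.  Diagonals are
one minus the listed exits, and a row whose exits exceed one is rejected
naming the state and stratum.  Two structural assumptions follow from the
listed edges: untreated-but-diagnosed patients do not die without first
progressing, and pre-diagnosis states carry no death hazard — so inside
the chain a *slower* diagnosis transition mechanically defers death.  The
harm of delay enters through stage migration and the stratified
post-treatment hazards, not through diagnosis timing; counterfactual
life-year deltas must be read with that in mind.

Numerical conventions: membership is counted at cycle start with **no
half-cycle correction** (simplest convention, switchable by construction
since the trace retains every row); discounting compounds the 3.5% annual
rate exactly, d(t) = 1.035^(−t/12); a 12-cycle trace of one alive state
with utility 1 therefore accumulates exactly one (quality-adjusted)
life-year undiscounted.  Costs: continuing-care (4,200 SAR) and
progressive-disease (18,700 SAR) costs accrue per cycle of occupancy;
diagnostic (2,450 SAR), initial-treatment and terminal-care (23,500 SAR)
costs attach to state *entries*, computed exactly from the transition
matrix when it is supplied and otherwise approximated by nonnegative
occupancy increments.  The initial-treatment range 15,300–42,800 SAR is
resolved linearly by stage at diagnosis (low = stage I, high = stage IV).

Calibration: transition MLEs are transition counts over person-months at
risk, overall and per stratum; a state never observed yields a *missing*
entry (not zero), and `TransitionTable.merged` fills gaps from a fallback
table.  A vectorised microsimulation provides the stochastic oracle: its
occupancy estimates converge to the deterministic trace at the binomial
rate, which the tests verify at n = 200,000.

## Mediation decomposition

The decomposition treats the mediators as causally ordered — stage
migration, then treatment intensity, then complications — and works on a
linear (log-hazard) scale, since no regression form is mandated by the
problem itself.  In the default *sequential* mode, a_k is the marginal
exposure→mediator coefficient (adjusted for confounders only), so each
product a_k·b_k captures every path that enters the outcome through
mediator k, and the ordinary-least-squares omitted-variable identity makes
the split exactly additive: total = direct + Σ a_k·b_k to machine
precision, with pathway shares summing to one.  A *parallel* mode that
additionally conditions each mediator model on the earlier mediators is
available; its attribution is per direct edge and only approximately
additive.  Confidence intervals are percentile bootstrap (not BCa) with
1,000 seeded replications by default.  Every result object carries the
non-collapsibility caveat: shares computed on the linear working scale do
not transport to hazard-ratio scales.  Mediators must be binary or
ordinal (at most 10 distinct levels); a zero total effect makes shares
undefined and is flagged as an error rather than returned as NaN.

Backdoor adjustment sets are enumerated exhaustively over non-descendants
of the exposure, testing each candidate set by d-separation in the graph
with the exposure's outgoing edges removed, and keeping inclusion-minimal
sets in a deterministic (size, lexicographic) order.  This is exponential
in the candidate count and intended for diagrams of the size used here
(10 nodes); the test suite cross-checks it against an independent
path-blocking oracle.

## Survival estimation

Kaplan–Meier curves use the product-limit estimator with right censoring;
without censoring they coincide with the empirical survival function
exactly.  The proportional-hazards fit maximises the Cox partial
likelihood with **Breslow** tie handling — adequate for continuous
simulated times, and simpler than Efron — via delay-category indicator
variables against the under-two-week reference.  Life-years lost is the
restricted-mean survival difference over the 120-month horizon (step
integration of the KM curves, divided by 12), sharing the Markov model's
timescale.  The published per-category life-year and QALY-loss values
(0.7–6.7 and 0.8–7.6 years) are carried as reference constants for the
weighted-average report: they exceed what the published hazard ratios
imply over a 10-year restricted horizon under any baseline we examined,
and the QALY losses exceed the life-year losses despite sub-unity
utilities, so neither is re-derived.  Validation statistics implement the
standard formulas — Hosmer–Lemeshow over 10 equal-count risk deciles with
χ²(bins − 2) p-values, rank-based concordance, MAPE over nonzero
observations, RMSE.  Their published values depended on the original
records and external datasets and are not reproduced.

## Reporting conventions

Percentages are reported at one decimal by truncation — which is what the
reference reports use: 470/639 = 73.55% appears as 73.5% — life-years at
two decimals, and the Cochran sample size n = z²p(1−p)/d² is floored
(384 at z = 1.96, p = 0.5, d = 0.05).  The count-weighted average
life-years lost over the delay distribution is
(45·0 + 84·0.7 + 40·1.2 + 241·2.8 + 60·4.3 + 169·6.7)/639 = 3.40 years.
The high-risk percentage is emitted under both published denominators
(470/639 and 589/802, which disagree in attribution but both round near
73.5%), labelled explicitly.  Every report table carries a provenance
entry (operation name plus an input hash) and the bundle records seed,
config hash and wall time; rerunning with the same seed reproduces every
cell bit-identically.

## Problem sizes

Defaults used by the tests and the acceptance script: cohorts of 20,000
patients for hazard-gradient and mediation recovery (sampling error well
inside the published confidence intervals), 1,000 bootstrap replications,
200,000 microsimulation paths for the trace oracle, and 5,000 histories
for transition-MLE recovery.  These sizes make the stochastic checks
sharp while keeping a full run to seconds on a single CPU.

## Known limitations

* The cohort generator draws mediators and survival independently given
  delay category; it does not encode mediator→survival structural effects,
  so the patient-level cohort is not itself a mediation ground truth (the
  calibrated linear-path generator serves that purpose).
* Single-step stage migration ignores double jumps over very long delays.
* No probabilistic sensitivity analysis, tunnel states, time-varying
  covariates, competing risks, or exposure–mediator-interaction
  (natural-effects) decompositions.
* The Markov chain's lack of pre-diagnosis mortality makes
  diagnosis-timing counterfactuals structurally optimistic about delay,
  as discussed above.
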