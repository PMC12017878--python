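# oncodelay

Causal and cohort-model analysis of diagnostic delays in breast cancer.

Delays between symptom recognition and definitive diagnosis let tumours
progress: a stage-I lesion diagnosed after a year carries a very different
prognosis than the same lesion diagnosed in two weeks, and the damage
accrues at different speeds in different molecular subtypes (triple-negative
fastest, HER2+ intermediate, hormone-receptor-positive slowest).
`oncodelay` packages the quantitative machinery needed to study this
problem — for epidemiologists and health-system modellers who want to set
subtype-specific maximum acceptable diagnostic intervals:

* **Synthetic cohorts** (`oncodelay.synth_cohort`) — seeded patient-level
  tables with the delay distribution, subtype mix, delay-dependent stage
  migration, mediators and proportional-hazards survival of a symptomatic
  breast-cancer cohort, so the whole pipeline is testable without patient
  records.
* **Stage migration** (`oncodelay.migration`) — cumulative upstaging
  probability P(migrate | delay d) interpolated through published
  1/3/6/12-month anchors, the *critical delay threshold*
  min{d : P(d) ≥ 0.10}, and the number needed to treat NNT = ⌈1/ARR⌉.
* **Markov cohort model** (`oncodelay.markov`) — five monthly-cycle health
  states (Symptomatic-Undiagnosed → Diagnosed-Untreated →
  Treatment-Initiated → Progressive-Disease → Death), stratified transition
  probabilities, maximum-likelihood calibration from event histories,
  cohort traces with discounted life-years, QALYs (utility weights
  0.78/0.70/0.65/0.45) and phase costs, counterfactual scenario deltas,
  and a microsimulation oracle.
* **Causal mediation** (`oncodelay.causal_dag`) — the study DAG, minimal
  backdoor adjustment sets verified by d-separation, and the product
  method: for each mediator k, the indirect effect is a_k·b_k (exposure→
  mediator times mediator→outcome coefficients from linear working models
  on the log-hazard scale), with direct effect c′ and percentile bootstrap
  CIs; shares satisfy c = c′ + Σ a_k·b_k exactly.
* **Survival** (`oncodelay.survival`) — Kaplan–Meier curves, Cox partial
  likelihood (Breslow ties) for the per-delay-category hazard-ratio
  gradient, restricted-mean life-years lost, and validation statistics
  (Hosmer–Lemeshow, concordance, MAPE, RMSE).
* **Reporting** (`oncodelay.report`, `oncodelay.cli`) — the end-to-end
  pipeline with a provenance-tracked report bundle and a `oncodelay`
  command-line interface (`simulate`, `markov`, `thresholds`, `mediate`,
  `survive`, `report`).

## Worked example

```bash
oncodelay --seed 1 thresholds
```

```
Stage I->II: computed day 78 (published reference 56), NNT 9 (published 9)
Stage II->III: computed day 107 (published reference 68), NNT 13 (published 13)
Stage III->IV: computed day 150 (published reference 73), NNT 18 (published 14)
HR+: computed day 134 (published reference 85), NNT 16 (published 16)
TripleNegative: computed day 57 (published reference 38), NNT 7 (published 6)
HER2+: computed day 79 (published reference 52), NNT 9 (published 10)
```

Each line evaluates one migration curve: the *computed* day is the first
integer day at which the linearly interpolated cumulative migration
probability reaches 10%, and the NNT is ⌈1/p₃ₘₒ⌉ — how many patients would
need an expedited work-up (replacing a typical three-month interval) to
prevent one upstaging.  The published reference thresholds are carried
alongside because they are not derivable from the published anchor
probabilities under any interpolation scheme; the two columns are reported
side by side, not reconciled (see `docs/methods.md`).

```bash
oncodelay --seed 1 mediate -n 20000 --n-boot 200
```

```
stage_migration: 67.9% of total effect (95% CI 65.5-70.5%)
treatment_intensity: 19.3% of total effect (95% CI 18.2-20.7%)
complications: 7.3% of total effect (95% CI 6.6-8.1%)
direct: 5.6% of total effect (95% CI 2.6-8.0%)
```

On a 20,000-patient synthetic cohort generated with path products set to
the published decomposition (67.3 / 18.9 / 7.4 / 6.4% of the total effect),
the product-method estimator recovers each pathway share with its
percentile-bootstrap interval covering the generating value: stage
migration dominates, treatment intensification is secondary, surgical
complications minor, and a small direct effect remains.

```bash
oncodelay markov
# life-years=1.876 qalys=1.113 cost=251,615 SAR
```

runs the overall-stratum cohort trace over the 10-year horizon (120
monthly cycles, 3.5% annual discount) for a cohort starting symptomatic
and undiagnosed.

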