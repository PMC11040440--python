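# riskgroups

Discovery and temporal validation of high-mortality child subgroups in
HDSS-style cohorts.

Health and Demographic Surveillance Systems (HDSS) register births, deaths
and migrations for whole urban or rural populations, and are often the only
individual-level data source in high-mortality settings.  `riskgroups`
implements, as a tested and reusable pipeline, an inductive–deductive
workflow for such data: discover candidate subgroups of children at
elevated risk of dying between 6 weeks and 3 years of age on an early
("hypothesis-generating") birth cohort, then re-test the frozen candidates
on a later ("temporal validation") cohort.  All effects are additive
mortality risk differences (MRD), expressed as deaths per 100 children.

The pipeline combines:

- **Inverse probability of censoring weighting (IPCW).**  Children who
  emigrate before age 3 have unknown outcomes; when emigration depends on
  baseline covariates the complete-case risk is selection-biased.  Each
  uncensored child is weighted by `w_i = 1 / P(uncensored | X_i)`
  (unstabilized, truncated), reconstructing the pseudo-population without
  emigration.
- **Kaplan–Meier risks** for overall and age-split cumulative mortality,
  with Greenwood variance and log(−log) confidence intervals.
- **Spatial sliding-window risk mapping.**  A 250 m × 250 m window slides
  in 10 m steps; each window's birth-year-adjusted risk is mapped, windows
  with fewer than 100 children are masked, and local maxima propose
  candidate high-risk residential circles.  Window sums use an integral
  image, exactly equivalent to the brute-force loop.
- **Backdoor-adjusted single-factor risk differences.**  Covariates live in
  an ordered causal hierarchy (environmental → household → individual/birth);
  the adjustment set for an exposure is calendar time plus all upstream
  domains.  Estimation is a weighted linear-probability model with sandwich
  standard errors.
- **Causes of Outcome Learning (CoOL).**  A non-negative one-hidden-layer
  network `p_i = clamp(R_b + Σ_h w2_h · relu(Σ_f W1_fh x_if + b_h), 0, 1)`
  decomposes each child's excess risk above the baseline `R_b` into
  per-feature risk contributions, clusters children on their contribution
  profiles (size-weighted Ward), and summarizes high-risk clusters as
  conjunction rules — the stage that surfaces multifactorial subgroups a
  population-average regression misses.
- **Targeted maximum likelihood estimation (TMLE).**  A from-scratch,
  doubly robust estimator of the subgroup risk difference
  `ψ = E_W[Q̄*(1, W) − Q̄*(0, W)] × 100`, with logistic outcome and
  propensity models, a logistic fluctuation with clever covariates `A/g(W)`
  and `(1−A)/(1−g(W))` solved by Newton iteration (the influence-curve
  equation holds to < 1e−8), and influence-curve standard errors.
- **Synergy, similarity and attributable fraction.**  Additive interaction
  (the conjunction's excess above its components' summed effects),
  a two-sample z-test for similarity of cohort estimates, pooled combined
  estimates, and the population attributable fraction
  `PAF = 100 · prevalence · aMRD / overall risk`.

Because real HDSS child records are not publicly deposited, the package
includes a first-class synthetic cohort generator (`riskgroups.simulate`)
with the same structure — a three-domain covariate hierarchy, a linear
mortality decline by birth year, one spatial hotspot, one single risk
factor, one two-factor synergistic subgroup, and informative emigration —
so every stage can be tested against known ground truth.

## Worked example

Run the full pipeline on the packaged demonstration configuration
(a 10,000-child synthetic cohort):

```sh
riskgroups all --config configs/demo.yaml --out out/
```

which prints

```
simulated n=10000 children (seed=1)
hypothesis: n=4746, weighted n=6396, mean weight 1.348, truncated 0
validation: n=2690, weighted n=3603, mean weight 1.340, truncated 0
discovery proposed 13 candidate rules (digest 1b6c8f89d449)
  [spatial] within 250 m of (645, 555)
  ...
  [single_factor] no_prenatal_consultations
  [cool] twin
  ...
wrote out/summary.csv (13 rules)
```

The IPCW step inflates each cohort by roughly one third (the mean weight
1.35 says a typical child stands in for 1.35 children once emigration is
undone).  Discovery on the 2003–2011 cohort proposes candidate subgroups
from all three analyses; the candidate list is frozen (content hash) before
the 2012–2016 cohort is touched.  `out/summary.csv` then scores every rule
on both cohorts.  Selected rows, with the planted truth in mind:

| rule | aMRD 2003–11 | aMRD 2012–16 | P(similar) | combined | PAF % |
|---|---|---|---|---|---|
| within 250 m of (645, 555) | 4.39 | 1.78 | .15 | 3.44 | 8.2 |
| no_prenatal_consultations  | 6.04 | 5.65 | .92 | 5.40 | 4.0 |
| twin                       | 6.42 | 5.51 | .82 | 7.00 | 4.4 |
| maternal_schooling_lt7     | 1.63 | 1.18 | .64 | 1.48 | 17.3 |

The first spatial circle sits about 155 m from the planted hotspot center
(700, 700) and recovers its +4 per-100 excess; the no-prenatal-consultation
factor recovers its planted +3.9 (plus sampling noise); and the common
low-education factor shows the familiar pattern of a modest risk difference
but a large attributable fraction because 60% of children are exposed.

Library use mirrors the CLI: `simulate.generate_cohort`,
`weights.fit_censoring_model` / `compute_ipcw`, `spatial.scan`,
`effects.tmle_risk_difference`, `cool.train_cool` /
`risk_contributions` / `extract_subgroups`, and
`pipeline.run_discovery` / `validate_candidates`.

## Layout

```
src/riskgroups/
  simulate.py   synthetic HDSS-like cohorts with planted ground truth
  weights.py    IPCW, Kaplan-Meier, crude risks, synergy statistic, PAF
  spatial.py    sliding-window risk surface, area effects, raster IO
  effects.py    backdoor adjustment sets, GLM and TMLE risk differences,
                similarity test, pooled estimates
  cool.py       Causes of Outcome Learning: non-negative network,
                risk-contribution decomposition, clustering, rules
  rules.py      serializable subgroup predicates with provenance
  pipeline.py   temporal split, discovery, frozen-candidate validation
  cli.py        riskgroups {simulate,weights,scan,validate,all}
docs/methods.md the model, defaults, and design choices in detail
```
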