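# Methods

This note documents the statistical model behind `riskgroups`, the defaults
that matter, what the synthetic generator does and does not emulate, and
the design choices made where the design was genuinely open.

## Study design and effect scale

The package analyzes a child-level cohort: one row per child with baseline
covariates recorded by 6 weeks of age, household coordinates in projected
meters, a censoring indicator (emigrated before age 3, outcome unknown) and
a death indicator for 6 weeks–3 years.  Follow-up starts at 6 weeks so that
baseline information exists for everyone; no deaths before entry appear in
a valid table, and covariates are complete (a complete-case design —
multiple imputation is out of scope).

Every effect is an additive mortality risk difference (MRD) per 100
children with a symmetric 95% Wald interval.  Risk differences, not ratios,
because they add across causes, feed directly into the attributable
fraction, and are what an intervention planner needs.

The workflow is inductive–deductive: candidate subgroups are discovered on
the earlier birth cohort (default: births through 2011) and re-scored on
the later cohort (2012 onward).  The candidate list is frozen with a
SHA-256 content hash before the validation cohort is touched;
`validate_candidates` refuses a list whose hash does not match the
discovery artifact, and a pipeline invariant test tampers with the artifact
to confirm the refusal.  Discovery never reads validation outcomes.

## Censoring weights

Emigration is treated as a single binary event (left the area before age
3), not as a time-varying process: emigrants' outcomes are unknown and the
remaining children are reweighted.  The censoring model is a logistic
regression of emigration on all baseline covariates.  Weights are
unstabilized inverse probabilities `w = 1/P(stay | X) ≥ 1`, so the weighted
sample is larger than the uncensored one — with the default ~24% emigration
a 21,005-child raw sample weights up by about a third.  Stabilized weights
would average 1 and lose that pseudo-population reading.  Weights are
truncated at 10 by default (configurable); diagnostics report the maximum,
mean and truncation count so "weights are not extreme" is checkable, not
assumed.  A property test plants covariate-driven emigration and verifies
that the weighted death risk matches the pre-emigration truth while the
complete-case risk shows the planted bias.

Perfect separation in the censoring model is an error naming the covariate;
zero censored children yield the trivial model P=0.

## Kaplan–Meier risks

Overall and age-split risks come from the Kaplan–Meier estimator
(`lifelines`), with emigrants censored at their observed age and survivors
administratively censored at 3 years.  The reported risk is
`(1 − S(t)) × 100` with the Greenwood standard error and the log(−log)
confidence interval.  With no censoring before the horizon this reduces
exactly to the empirical proportion (tested).

## Spatial scan

A 250 m × 250 m window slides in 10 m steps over the bounding box.  Choices
the window definition leaves open, fixed here:

- **Half-open windows** `[x, x+250) × [y, y+250)` so overlapping windows
  treat boundary points consistently.
- **One global trend, not per-window fits.**  Mortality declines roughly
  linearly with birth year; a single weighted linear-probability regression
  on `(birth_year − reference)` is fitted once, and each window averages
  per-child residuals: node value = (global risk at the reference year +
  weighted mean residual) × 100.  Per-window year fits would be unstable at
  the 100-child minimum.
- **Reference year** = midpoint of the observed birth-year range.
- **Masking** uses the unweighted child count (< 100 children → masked);
  weighted counts still drive the estimates.  Raising the threshold can
  only mask more nodes (tested monotone).

Window sums use a summed-area table over 10 m cells; an oracle test checks
exact equality with a brute-force double loop on a 50 × 50-node grid.
Surfaces export as ESRI ASCII grids (NODATA for masked nodes) or float32
TIFF, round-tripping losslessly at float32.  Candidate high-risk areas are
circles of default radius 250 m around greedy non-overlapping local maxima
exceeding the global risk by a configurable excess (default 2 per-100);
the delineation is a convenience, not an inference — area effects are
estimated afterwards as calendar-adjusted risk differences for inside
versus outside.

## Adjustment sets and single factors

Covariates belong to one of three ordered domains — environmental,
household, individual/birth — mirroring the assumed data-generating
hierarchy.  The backdoor adjustment set for an exposure is calendar time
plus every covariate in the domains strictly upstream of the exposure's
own; sex and birth season are treated as unconfounded (empty set).
Single-factor effects are weighted linear-probability regressions with
HC1 sandwich standard errors: the linear-probability form targets the risk
difference directly, and identity-link binomial fits fail to converge
routinely on data like these.  With an empty adjustment set and unit
weights the estimate equals the crude risk difference algebraically.

## TMLE

`tmle_risk_difference` estimates `ψ = E_W[Q̄(1,W) − Q̄(0,W)] × 100` for a
binary subgroup indicator A:

1. Initial outcome model: weighted main-effects logistic regression of
   death on A and W (a deterministic parametric learner, not an ensemble;
   a hook for pluggable learners is the natural extension).
2. Propensity: weighted logistic regression of A on W, truncated to
   [0.01, 0.99]; the truncated fraction is reported and > 5% raises a
   diagnostic flag.
3. Fluctuation: logistic regression of death on the clever covariates
   `H1 = A/g(W)` and `H0 = (1−A)/(1−g(W))` with `logit Q̄` as offset.  The
   two-parameter problem is solved by a dedicated Newton iteration on the
   weighted score rather than a generic GLM routine, because the package
   asserts the efficient-influence-curve equation `|mean(IC)| < 1e−8` on
   every fit and IRLS stopping rules do not guarantee it.
4. `ψ` is the weighted mean of targeted differences; the standard error is
   `sqrt(Σ w² IC²)/Σ w`, which treats IPCW weights as frequency weights
   consistently with their use in every regression.

With W empty, TMLE, the GLM and the crude difference agree to numerical
precision (tested).  A simulation suite checks unbiasedness on planted
confounding (truth 4.0 per-100 with the crude estimate biased by ~1.8) and
95% CI coverage within 95% ± 4% over 200 replicates at n = 50,000.

Cross-cohort comparison uses a two-sample z-test,
`z = (ψ₁ − ψ₂)/√(se₁² + se₂²)`; the test refuses estimates tagged with the
same cohort.  This functional form was adopted after verifying that,
applied to published cohort estimates with standard errors reconstructed as
CI-width/3.92, it reproduces eight independently printed P values within
±0.03 (a regression test keeps that reconstruction true).  Combined
estimates pool the two cohorts at the individual level (disjoint child ids
enforced) and rerun TMLE with calendar time forced into W; pooling at the
data level rather than meta-analyzing the two estimates reproduces the
published combined value more closely.  No multiple-testing correction is
applied anywhere — the discovery stage is explicitly exploratory, and the
temporal validation is the error control.

## Causes of Outcome Learning

The multifactorial stage fits a constrained one-hidden-layer network

    p_i = clamp(R_b + Σ_h w2_h · relu(Σ_f W1_fh x_if + b_h), 0, 1)

with `W1 ≥ 0`, `w2 ≥ 0`, `b ≤ 0`, `R_b ∈ [0,1]`.  The constraints make the
model monotone: features can only add risk above the baseline, and a hidden
unit with negative bias behaves as a soft AND gate that fires only for
feature combinations — which is what makes the approach sensitive to
synergy in subpopulations.  Calendar time enters as birth-year band
indicators (default 3-year bands) so that period effects are absorbed by
the network instead of confounding covariate contributions.

Training minimizes weighted squared error by full-batch Adam (step 0.01,
default 400 epochs with early stopping on a relative-loss plateau) with
projection after every step (negative `W1`/`w2` entries to 0, `b` capped at
0, `R_b` clamped to [0,1]); the best of 10 seeded restarts is kept, and
results are bit-reproducible given (data, hyperparameters, seed).  The
defaults — 10 hidden units, squared-error loss, 10 restarts — are
documented, overridable settings, chosen for desk-scale determinism rather
than tuned per data set.  Divergence (non-finite loss) is an error
suggesting a smaller learning rate.

Each child's excess risk decomposes into per-feature contributions by
attributing every unit's output to its active features in proportion to
their share of the positive pre-activation:
`c_if = Σ_h w2_h · relu_h · (W1_fh x_if / Σ_f' W1_f'h x_if')`.  A firing
unit necessarily has a positive pre-activation sum (biases are ≤ 0), so the
share is always defined.  The decomposition is complete by construction —
baseline + contributions + clamp residual = prediction, asserted to 1e−10
per child — and a feature contributes nothing wherever it is absent.

Children are clustered on their contribution profiles with Ward linkage.
Because binary inputs make profiles heavily repeated, the linkage runs on
deduplicated (rounded) profiles weighted by multiplicity, which is exactly
Ward on the full cohort at a fraction of the cost; the merge table is cut
to the requested number of groups.  Groups below 0.5% prevalence are kept
but flagged "very few children" and excluded from validation candidates.
A cluster becomes a conjunction rule over the features whose group-mean
contribution reaches half the group's top contribution (threshold
configurable; at threshold ≥ 1 ties break alphabetically; calendar bands
never define rules).

Known limitation: when two additive factors overlap, the overlap stratum
has a distinct contribution profile, and overcutting the tree promotes it
to a spurious conjunction rule.  The size-weighted tree absorbs such strata
into the nearest single-factor group at parsimonious cuts, and the
downstream synergy statistic — the conjunction's coefficient alongside its
components' main effects and calendar time, with sandwich errors — is the
explicit guard: it is centered at zero under additivity (tested) and at the
planted excess under synergy.  Total effects can also be diluted across
correlated features sharing hidden units; contributions are attribution
shares, not causal effects, and every proposed rule is therefore re-scored
with TMLE.

## Synthetic cohort generator

The generator is the package's ground-truth instrument, emulating the
structure of an urban West African HDSS cohort: ~21,005 children born
2003–2016 over a 3 km × 3 km area, risk declining from roughly 5 to 3 per
100 across the period, a three-domain covariate hierarchy with realistic
prevalences (61% low maternal schooling, 83% crowding, 18% polygamous
household, 3% twins, 4% no prenatal consultations, five ethnicity levels,
~50/50 dry/rainy birth season), one spatial hotspot (radius 200 m, +4
per-100, doubled residential density), one elevated single factor (no
prenatal consultations, +3.9), one synergistic pair (twin × rainy season,
+6.8 beyond the main effects), and logistic emigration on baseline
covariates calibrated so IPCW inflates the cohort by about a third.

Design choices:

- **Additive risk on the per-100 scale**, not logistic: planted increments
  are then exactly the risk differences the estimators target, so recovery
  tests have sharp truths.  The cost is that configurations must keep every
  covariate pattern's risk inside [0, 1]; a pattern that exits the range is
  a configuration error naming the pattern, never a silent clamp (clamping
  would corrupt the ground truth).
- The baseline (4.5 per-100 at 2003, −0.33/year for the all-reference
  child) was set so that after adding the mean covariate load the two
  cohort-level risks land near 5.2 and 2.9 per-100.
- Covariates are independent by default; optional logistic links let
  household covariates depend on environmental ones and birth covariates on
  both, respecting the domain ordering.
- Death and censoring use separate random draws *after* all covariates, so
  toggling censoring does not perturb outcomes for the same seed; the same
  seed yields a byte-identical table.
- Event and censoring ages are uniform on (6 weeks, 3 years]; they carry no
  planted age structure, so age-split analyses on synthetic data test
  mechanics, not biology.

What the generator does not emulate — and hence what passing tests do not
show about real data: real geography and migration flows, registration
system changes, seasonal and epidemic mortality structure, correlated
covariate patterns beyond the optional links, and measurement error or
missingness (the generator is complete-case by construction).

## Problem sizes and numerical conventions

Simulation tests run at n = 50,000 where a 3·standard-error recovery bound
is asserted, and 10–200 seeded replicates for recovery-rate and coverage
properties; the packaged demo uses a 10,000-child cohort over a denser
1.5 km square so spatial windows clear the 100-child mask.  Further
conventions: propensities truncated to [0.01, 0.99]; probabilities clipped
to [1e−6, 1−1e−6] before logits; the fluctuation Newton iterates to a
score below 1e−12 per unit weight; "very few children" suppression at 20
children per cell; hierarchical cuts by exact cluster count (tied merge
heights make threshold-based cuts skip counts).  All randomness flows from
explicit integer seeds through `numpy.random.default_rng`.
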