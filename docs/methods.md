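# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the known limitations of `demprev`.

## Measurement model

Two samples answer overlapping item sets: a large survey (group A) and a
small validation sample (group B) nested within it. Each item loads on
exactly one of two latent dimensions — cognition or function (simple
structure); cross-loadings are out of scope. Binary items follow the
two-parameter logistic model and ordinal items the graded response model,
both in the logistic metric. For an ordinal item with K categories the
cumulative curves σ(a·θ_f + d_k) share one slope, so they never cross and
category probabilities are always non-negative; intercepts are kept
strictly decreasing throughout estimation.

Two derived parameterizations are reported because they are the ones
practitioners read:

- loading λ = (a/D)/√(1+(a/D)²), with the conventional normal-ogive
  rescaling constant D = 1.702 (configurable). λ lies in [0, 1) and is the
  standardized item–trait correlation under simple structure.
- thresholds b_k = −d_k/a, the ability level at which the k-th category
  boundary is crossed with probability one half.

## Multiple-group estimation

The joint likelihood over both groups is maximized by EM over a fixed
rectangular tensor-product quadrature grid. Identification: group B (the
validation sample) is the reference, with latent distribution fixed at
N(0, R(ρ)) with free correlation ρ — one unit of ability is one
validation-sample SD. Group A's mean vector and full covariance are free.
Anchor items (administered in both samples) carry a single parameter set;
their expected-count tables are pooled across groups in the M-step, which
is what places the two samples on one scale.

Numerical design:

- **Grid**: 31 equally spaced nodes per dimension on [−5, 5], prior weights
  recomputed each cycle from the current latent specification. 31 nodes
  keeps the default-grid EAP scores within ~6e-5 of a 201-node refinement
  even for the sharpest posteriors the default item bank produces
  (posterior SD ≈ 0.32 for function); a 21-node grid leaves ~2e-3 aliasing
  error and fails the package's own 1e-3 accuracy check. The grid is
  refinable via configuration.
- **E-step**: under simple structure a person's likelihood factorizes into
  a cognition part times a function part, so all posterior summaries are
  outer-product contractions costing O(n·m²) for m nodes rather than
  O(n·m²·items). This is exact, not an approximation.
- **M-step, items**: damped Newton ascent (max 50 inner iterations) on the
  expected complete-data log-likelihood per item, with analytic gradients,
  finite-difference Hessians, and step-halving that also enforces slope
  positivity and intercept ordering. Items observed in only one category
  are dropped with a warning (their slope MLE is unbounded).
- **M-step, latent**: the prior enters the discretized likelihood through
  normalized grid weights, so the latent update maximizes the
  normalized-weight objective directly (bounded scalar search for ρ in the
  reference group; Nelder–Mead over mean/log-SD/atanh-correlation for the
  focal group), accepting an update only if it does not decrease the
  objective. Together with step-halving in the item updates this makes the
  EM a generalized EM: the discretized marginal log-likelihood is
  non-decreasing up to floating-point accumulation (~1e-10 relative).
- **Convergence**: stop when the largest parameter change in a cycle falls
  below 1e-4, or when a full cycle improves the log-likelihood by less than
  5e-4 (the plateau criterion; at the default scale the parameter-change
  norm decays by only ~1% per cycle long after the likelihood has
  flattened), with a cap of 800 cycles. The recovery-scale fit converges in
  ~65 cycles; the default-scale fit in ~550.
- **Start values**: unit slopes; intercepts at the pooled marginal
  cumulative log-odds.

Items with fitted loading below 0.3 are removed and the model refitted
(warm-started) until none remain — a fixed point, since one removal changes
other items' loadings only slightly. Reliability per factor is McDonald's
ω = (Σλ)²/((Σλ)² + Σ(1−λ²)) from the standardized loadings with
uncorrelated uniquenesses.

Factor scores are EAP estimates — posterior means over the grid, with
posterior SDs from second moments. Each person is scored under the prior of
the group whose matrix retains them; overlap persons live in the validation
matrix only (see below) and are therefore scored under the reference prior.
A person with no observed responses returns the prior mean. Note EAP
estimates are shrunken: their variance is the prior variance times the
score reliability, so SD(EAP) ≈ 0.91–0.94 in the reference group, while
Var(EAP) + E[posterior SD²] reconstructs the unit prior variance.

## Data preparation

- Continuous items are discretized into ten equal-width bins over the
  observed pooled range (right-closed top bin), then treated as ordinal.
- Categories holding under 5% of the pooled (A+B) non-missing responses are
  merged with their smaller adjacent neighbour (lower index on ties) until
  all categories clear the floor or only two remain. Pooling keeps anchor
  items' category structures identical across groups; merges are monotone,
  so they never reorder two persons' underlying values.
- Persons lacking any valid response in either domain are excluded
  (counted per domain in the audit log), since a latent score in a domain
  requires at least one observed item.
- Persons present in both samples are kept only in the validation sample's
  matrix, so each individual contributes one record to the joint model.

## Classification and prevalence

The three logistic variants (base: age + sex; factor: the two EAP scores;
full: all four) are fitted by IRLS with survey weights multiplying the
score equations (step-halved Newton; tolerance 1e-10), and a design-based
sandwich covariance clustering score totals on PSU within stratum (strata
with a lonely PSU are centered at the grand mean; a model-based inverse
information is available as an option). AIC is computed from the weighted
pseudo-log-likelihood with raw weights and is therefore design-dependent —
it orders models on one consistent estimation sample, and is not
comparable across weighting schemes. The Hosmer–Lemeshow statistic
normalizes weights to the sample size so it is invariant to uniform weight
rescaling, as are all reported metrics.

Cross-validation uses outcome-stratified, seeded folds and pools
out-of-fold predictions before computing metrics (pooling is more stable
than per-fold averaging at n ≈ 750). Metrics are survey-weighted by
default, with unweighted companions reported alongside. Uncertainty comes
from 1000 draws of the coefficient vector from N(β̂, V̂); the 95% interval
is the 25th/975th order statistics of the per-draw metrics (rank
ceil(0.025n)/ceil(0.975n) for other draw counts; at least 40 draws are
required).

Dementia status in the large survey is predicted for every scored person —
overlap persons contribute their validation-group scores, and each person
is counted once under the large survey's design. Status is 1 iff the
predicted probability strictly exceeds 0.5. Prevalence is Σw·status/Σw per
group (overall, age band, age band × sex), with variance by stratified
Taylor linearization over PSU totals and a Wald interval truncated to
[0, 1] (a logit-scale interval is available).

## The synthetic generator

The generator emulates the structure the analysis assumes, at desk scale:

- Frame of N = 20,000 persons aged 70+, with age-band shares 70/27/3%
  (70–79, 80–89, 90+). Sex is 58% female.
- Latent abilities: bivariate normal residuals with correlation ρ = 0.6
  around linear age trends of −0.04 (cognition) and −0.05 (function)
  reference-SD per year past 70.
- Diagnosis: Bernoulli with logit p = b0 + b_cog·θ_cog + b_fun·θ_fun +
  b_age·(age−70) + b_sex·sex; defaults b_cog = ln 0.03, b_fun = ln 0.45
  per SD (the magnitudes a well-fitting classification model reports),
  b_age = 0 (age acts only through the latent declines, which is what makes
  the age-attenuation property testable), b_sex = ln 1.3. The intercept
  b0 = −7.5 was calibrated once against the generator itself to place
  overall prevalence near 10% with an age gradient of roughly 7/14/28%
  across the bands — the regime of interest; the steep per-SD effects
  force a deep intercept.
- Item bank: 20 cognition items (12 anchors, 2 continuous, one deliberately
  weak with slope 0.2 ≈ loading 0.12 to exercise pruning) and 12 function
  items (8 anchors); ~25% of discrete items are ordinal with 3–5
  categories. Cognition loadings are drawn U(0.35, 0.85) and function
  loadings U(0.70, 0.90) — function measured more reliably, as is typical
  of informant-reported limitation scales — with cognition thresholds
  pitched mostly below the mean (items target impairment).
- Design: survey A is a self-weighting simple random sample (n = 6000).
  The validation sample is a Poisson subsample of A with cell-specific
  inclusion probabilities over cognition-tertile × age-band cells
  (relative rates 3/1.5/1 across tertiles and 1/1.5/2 across bands,
  scaled to an expected n = 750), weights equal to inverse overall
  inclusion probabilities. Design strata for A are age bands with PSUs as
  random ~30-person blocks (never fewer than two per stratum); validation
  members inherit the parent survey's stratum/PSU identifiers, as nested
  validation studies do, so design-based variance propagates both sampling
  stages. The sampling cell is carried as an audit column.
- Missingness: responses deleted completely at random at 5% per domain;
  persons emptied of a domain are flagged for exclusion.

What the generator does **not** emulate: specific instruments or their
content, differential item functioning between groups, proxy-vs-self
measurement differences (a response-source column can be carried through
but nothing differs by it), non-MAR missingness, mortality or longitudinal
structure, and real survey geography (PSUs are synthetic blocks). Passing
tests therefore demonstrate that the *pipeline* recovers what it assumes;
they say nothing about instrument-specific biases in real data.

## Properties the test suite establishes

- Closed-form correctness of every response-probability, likelihood,
  loading/threshold and ω computation against independent algebra.
- EM monotonicity and convergence; EAP accuracy against grid refinement.
- Parameter recovery at n = 3000/group on a self-weighting version of the
  design (slope correlation ≥ 0.95, mean loading error ≤ 0.05, ρ within
  ±0.10, the planted weak item pruned). The self-weighting variant is used
  because under the informative design the reference group's true latent SD
  exceeds 1, so fitted parameters sit on a rescaled metric and absolute
  comparisons to the generating bank would conflate scale with error.
- Anchor-based linking: a +0.5 focal-group ability shift is recovered in
  the estimated focal latent mean.
- Design-based machinery: IRLS against an independent GLM implementation,
  AUC against O(n²) concordance, Hosmer–Lemeshow against the definition,
  leave-one-out equals a manual refit loop, coefficient CI coverage within
  [88%, 100%] over 50 replicates of the weighted design, and weighted
  prevalence unbiasedness (the unweighted estimate is inflated by ~7
  points under the default oversampling).
- End-to-end: the full default pipeline recovers population prevalence
  within 3 percentage points with a monotone age gradient.

## Known limitations

- **Threshold-rule prevalence bias.** Classifying at p > 0.5 biases
  predicted-status prevalence toward the majority class whenever
  discrimination is imperfect; expected prevalence E[p̂] is closer to
  unbiased. At the desk-scale bank (32 items, cross-validated AUC ≈
  0.93–0.95) the end-to-end gap ranges over ~1.8–4.8 points across
  generator seeds (≈1.8 at the defaults). With richer item banks —
  higher AUC — the bias shrinks; users estimating prevalence in earnest
  should prefer richer instruments or report E[p̂] alongside.
- The reference group is modeled as standard bivariate normal although the
  oversampled validation sample's true latent distribution is neither
  centered nor normal; this mild misspecification is inherent to the
  design (the reference prior defines the reporting scale) and slows EM
  convergence at the default scale.
- AIC under survey weights is a pseudo-likelihood quantity; its absolute
  value depends on the weight scale even though model ordering on one
  sample is consistent.
- Sandwich and linearization variances use the with-replacement
  approximation (no finite-population corrections); at the default
  sampling fractions this is mildly conservative.
- ω uses standardized loadings with uncorrelated uniquenesses; with
  correlated residuals it would overstate reliability.
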