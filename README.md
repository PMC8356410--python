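# demprev

Dementia prevalence prediction for linked surveys, by co-calibrated
multidimensional item response theory (IRT).

## The problem

Large population surveys of older adults typically measure cognitive
performance and daily functional limitations but do not adjudicate dementia
diagnoses; small validation studies nested inside them do. `demprev`
implements the estimation pipeline that bridges the two: it places both
samples on a common latent scale using the items they share, learns a
classification rule for dementia in the validation sample, and applies that
rule to the full survey to obtain design-weighted prevalence estimates by
age and sex. Because real linked survey data of this kind are
access-restricted, the package ships a synthetic-data generator that
reproduces the statistical structure of the problem — two linked samples
with shared anchor items, a validation subsample oversampled at low
cognition (hence informative weights), correlated latent traits declining
with age, item-level missingness, and a diagnosis driven by both traits —
with full ground truth retained, so every stage of the pipeline is testable
against known truth.

## The model

Each person carries a bivariate latent ability θ = (θ_cog, θ_fun). A binary
item *j* loading on factor *f(j)* follows a two-parameter logistic model

    P(X_j = 1 | θ) = σ(a_j θ_f(j) + d_j),

and an ordered K-category item follows the graded response model through
cumulative curves sharing one slope,

    P(X_j ≥ k | θ) = σ(a_j θ_f(j) + d_jk),   d_j1 > … > d_j,K−1.

Continuous items are first discretized into ten equal-width categories, and
any category holding under 5% of the pooled sample is merged with its
smaller adjacent neighbour.

The two samples are fitted jointly by marginal maximum likelihood (EM over
a rectangular quadrature grid): items administered in both samples (anchors)
are constrained to one parameter set, the validation sample is the reference
group with θ ~ N(0, R(ρ)) — so one unit is one validation-sample standard
deviation — and the larger survey's latent mean vector and covariance are
free. Slopes convert to standardized loadings λ = (a/D)/√(1+(a/D)²) with
D = 1.702; items with λ < 0.3 are pruned and the model refitted. Reliability
per factor is McDonald's ω. Persons are scored by expected a posteriori
(EAP) estimates with posterior SDs.

Dementia is then classified by survey-weighted logistic regression on the
validation sample (base: age + sex; factor: the two scores; full: all four),
with a stratified PSU-clustered sandwich variance, AIC/likelihood-ratio
comparison, Hosmer–Lemeshow calibration, ten-fold cross-validated
AUC/sensitivity/specificity/accuracy, and 95% uncertainty intervals taken as
the 25th/975th order statistics of 1000 parameter draws. The full model's
predictions (dementia iff predicted probability > 0.5) are applied to the
large survey, and prevalence is estimated as the Horvitz–Thompson weighted
mean with Taylor-linearized design-based confidence intervals, overall and
by age band × sex.

## Worked example

The numbered drivers under `analysis/` run the pipeline stage by stage on
the default synthetic scenario (frame N = 20,000; survey A n = 6000;
validation B expected n ≈ 750; 20 cognition + 12 function items, 20 of them
anchors), writing bulky artifacts under `scratch/pipeline/` and summary
tables under `results/`:

```bash
cd analysis
python 01_simulate.py
python 02_prepare_items.py
python 03_fit_irt.py
python 04_score.py
python 05_classify.py
python 06_prevalence.py
```

Output of the default run (abridged):

```
frame N=20000, survey A n=6000, validation B n=732
population dementia prevalence: 0.099
validation sample is informatively drawn: raw prevalence 0.184 vs weighted 0.107
...
retained 31 items (pruned 1 with loading < 0.3); converged: True
  cognition: loadings 0.34-0.93 (median 0.50)
  function: loadings 0.72-0.88 (median 0.78)
omega reliability: cognition 0.91, function 0.95
factor correlation (reference group): 0.670
...
odds ratios (full model):
  age: OR 1.02 (0.99-1.05)
  eap_cog: OR 0.04 (0.02-0.07)
  cross-validated auc: 0.945 (95% interval 0.945-0.949)
Hosmer-Lemeshow: chi2=3.08, p=0.929
...
design-weighted predicted prevalence:
     all: 8.1% (7.5-8.8), n=6000
   70-79: 6.2% (5.5-6.9), n=4165
   80-89: 11.8% (10.3-13.3), n=1658
     90+: 19.8% (17.6-21.9), n=177
generating population prevalence (ground truth): 9.9%
```

Reading the output: the raw validation-sample dementia rate (18.4%) is
nearly double the population rate because of the low-cognition
oversampling, and the survey weights correct it (10.7% vs 9.9% truth). The
fitted cognition score carries almost all the classification signal (OR
0.04 per reference-SD), the marginal age effect disappears once the scores
enter (OR 1.02), and the predicted prevalence recovers the generating 9.9%
to within two percentage points with the expected age gradient.

The same pipeline is scriptable end to end:

```bash
demprev run-all --out scratch/run1            # defaults
demprev write-config --out my.yaml            # edit, then:
demprev run-all --config my.yaml --out scratch/run2
```

`demprev validate` checks user-supplied CSVs against the input schema, so
the pipeline can also be pointed at real linked-survey data mapped to the
documented long format.

## Layout

- `src/demprev/` — the library: `synthetic_data`, `item_prep`, `irt_core`,
  `irt_fit`, `classifier`, `prevalence`, plus `config`, `pipeline`,
  `validation`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — model, assumptions, numerical choices, limitations.
- `tests/` — unit, property and end-to-end acceptance tests.
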