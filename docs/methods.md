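# Methods

`gendermech` estimates how much of the observed difference in adult biomarker
levels between male-born and female-born members of a birth cohort can be
attributed to *gendered* (social) rather than *sexed* (biological) mechanisms.
This note documents the statistical machinery, the synthetic-cohort generator
that makes the pipeline testable without restricted cohort data, and the
design choices made where the methodology was genuinely open.

## Data model

An analysis table holds, per individual:

* `sex` S — sex at birth, 1 = male-born, 0 = female-born;
* two early-life environment indicators (mother left school at 15; other
  parent in a manual social class at the member's birth) and their
  conjunction `deprived` E (the missing-aware rule: E = 0 as soon as either
  indicator is observed 0, E = 1 only when both are 1, otherwise missing);
* 21 binary socio-behavioural mediators Σ measured at ages 23/33, grouped as
  cultural capital (5), economic capital (3), social capital (5) and health
  behaviours (8), each coded 1 for the category more frequent among male-born
  members;
* six biomarkers at 44–45: systolic blood pressure (mmHg), triglycerides
  (g/L), LDL cholesterol (mmol/L), HbA1c (%), CRP (mg/L), cortisol (µg).
  The three right-skewed markers (triglycerides, CRP, cortisol) are analysed
  on the natural-log scale; natural log is a package choice (base is a
  reporting convention only). Effects are reported both in native units and
  in standard deviations, z = (y − µ)/σ with µ, σ the mean and SD of the
  outcome *in the dataset at hand* (each imputed bootstrap replicate
  standardizes itself).

Three nested mediator sets are predefined: `complete` (all 21),
`behavioural` (the 8 behaviours), and `small` (education 23, social class 33,
friends' visits 23, marital status 23, sport 33, fried food 33, smoking 33,
daily alcohol 33).

## Estimands and g-computation

All causal contrasts are differences of counterfactual means E[Y_{A=a}],
estimated by parametric g-computation: fit a linear outcome regression
Q̄(A, L) = E[Y | A, L] by OLS, substitute the scenario's assignments into
every individual's covariates, predict, and average over the empirical
distribution of the unassigned covariates. Identification rests on the usual
no-unmeasured-confounding and consistency assumptions; for sex at birth the
randomization assumption is natural, for the mediator-outcome relations the
early-life environment E is the measured confounder.

* **Total effect** TE = E[Y_{S=1} − Y_{S=0}], from Q̄(S, E) with an S×E
  product term.
* **Strategy (a), gender as an individual characteristic.** The gender
  score G is the "gender diagnosis": the predicted probability of being
  male-born from a main-effects logistic regression of S on the active
  mediator set, a continuum from 0 (predicted female) to 1 (predicted male).
  The controlled direct effect CDE^G = E[Y_{S=1,G=g₀} − Y_{S=0,G=g₀}]
  (default g₀ = 0.5) comes from Q̄(S, G, E); G enters linearly and without an
  S×G product, so CDE^G is invariant to g₀ (the test-suite asserts this
  rather than assuming it). The eliminated proportion is
  EP^G = (TE − CDE^G)/TE.
* **Strategy (b), gender as a sex effect on socio-behavioural
  characteristics.** CDE^Σ fixes the whole mediator vector at a reference
  profile ε* in Q̄(S, Σ, E) (main effects only, no S×Σ products, hence
  ε*-invariance). The default ε* is each mediator's modal category in the
  analysis dataset; any published profile can be supplied instead.
  EP^Σ = (TE − CDE^Σ)/TE.
* **Strategy (c), gender as a sex-by-environment interaction.** The stratum
  effect TE⁰ = E[Y_{S=1,E=0} − Y_{S=0,E=0}] is the remaining sex effect had
  everyone been born non-deprived (the a-priori "less gendered" environment);
  EP^E = (TE − TE⁰)/TE. The complementary additive interaction is
  IE = (Y₁₁ − Y₁₀) − (Y₀₁ − Y₀₀), identically TE¹ − TE⁰ and also the
  male-female difference of deprivation effects.

With the saturated S*E model every counterfactual mean equals an observed
(S, E) cell mean, so stratum effects, deprivation effects and IE are exact
cell-mean arithmetic — this is the oracle the acceptance tests exploit, and
it makes published per-cell tables directly reproducible.

EP is a ratio and explodes when TE ≈ 0. It is still reported (sign
convention: negative EP means the sex gap *widens* when the gendered pathway
is blocked) but flagged `unstable` whenever the bootstrapped TE interval
includes zero; TE exactly 0 yields NaN rather than a crash.

## Inference: bootstrap-then-impute

Uncertainty comes from B = 1,000 (default) bootstrap replicates. Each
replicate resamples n individuals with replacement, performs **one**
stochastic imputation of the resampled table, refits the gender-score model,
and recomputes every estimand. The point estimate is the replicate mean and
the 95% CI the empirical 2.5/97.5 percentiles (numpy's linear interpolation
of order statistics). A CI touching zero counts as non-significant.
Replicates draw child seeds spawned from one master seed, so runs are
reproducible and replicate order is immaterial. Failed replicates are
recorded and dropped; more than 5% failures aborts the run.

Imputation is chained equations, written in-repo and fully specified:
columns are visited in order of increasing missingness for a default 10
cycles; binary columns get a logistic fit on all other columns followed by a
Bernoulli draw, continuous columns an OLS fit plus a Gaussian residual draw.
Coefficients are not posterior-drawn and no predictive mean matching is used
— a deliberate simplification, adequate here because the bootstrap (not
Rubin's rules) carries the uncertainty. Log-scale biomarkers are imputed on
the log scale, where the data model is linear. Logistic fits carry a weak
ridge (λ = 1 on standardized predictors) for numerical stability; with
hundreds of observed rows this is indistinguishable from maximum likelihood.

The gender-score fit itself is unpenalized maximum likelihood (so the mean
fitted score equals the sample male prevalence). Complete separation —
realistic only in tiny tables — triggers a flagged ridge refit with fixed
strength λ = 0.1 on the mediator coefficients, never a silent one.

A `complete_cases: true` pipeline option restricts the analysis to rows
fully observed on the variables actually used and never imputes, mirroring
a complete-attendance sensitivity analysis (attendance itself is not a
property synthetic data can have).

## Synthetic cohort generator

The generator emulates a 1958-style national birth cohort with known causal
structure so that every estimator can be checked against closed-form truth:

* S ~ Bernoulli(0.51); the two environment indicators are Bernoulli(0.75)
  and Bernoulli(0.73) coupled with odds ratio 3 (social clustering), giving
  P(E=1) ≈ 0.58;
* each mediator follows logit P(Σⱼ=1 | S, E) = αⱼ + βⱼS + γⱼE ("gender
  pressure" is the βⱼ); αⱼ and βⱼ are calibrated so the by-sex prevalences
  reproduce the descriptive table of the emulated cohort (sex gaps of
  0.3–82 percentage points);
* each biomarker is linear on its analysis scale,
  y = a + bS + cE + dSE + Σⱼ wⱼΣⱼ + Normal(0, σ_y), exponentiated for the
  log-scale markers. Sex effects b are 0.05–0.75 SD, deprivation effects c
  positive and smaller, interactions d about −0.1 to +0.01 SD, matching the
  magnitudes the pipeline is meant to resolve;
* MAR missingness: per-column logit models whose predictors are restricted
  to the always-observed columns (sex and the two environment indicators) —
  a model referencing a maskable column is rejected as MNAR. Default rates
  emulate a heavy biomedical-wave burden: ≈ 40–48% for biomarkers, ≈ 17–23%
  for mediators.

Deprivation shifts γⱼ and mediator weights wⱼ have no published counterpart;
they are one-time calibration choices recorded in
`gendermech.synthetic` and exportable/overridable via YAML scenarios.

`compute_truth` returns, per biomarker: TE, CDE^Σ (= b + d·P(E=1) under this
generative model), TE⁰, TE¹, IE, EP^Σ, EP^E in closed form (marginalizing
the logit mediator responses over E), the population SD (total-variance law,
for z-scale truths), and a Monte-Carlo value for CDE^G. CDE^G has no closed
form because the score is a nonlinear function of Σ; its "truth" is defined
as the large-sample value of the estimand itself, computed on a 200,000-row
simulated cohort using the exact Bayes posterior P(male | Σ) (enumerating
the four (S, E) cells of the conditionally independent mediator model — no
fitted score) followed by the linear Q̄(S, G, E) contrast, with a
chunk-splitting MC standard error.

What the generator does **not** emulate: longitudinal attrition and
mortality selection, wave structure beyond "mediators at 23/33, outcomes at
44–45", residual mediator-mediator dependence given (S, E), non-Gaussian
biomarker noise beyond lognormality, and MNAR mechanisms. Tests passing on
synthetic data therefore establish the estimators' correctness under the
stated model, not robustness to those real-data features.

## Numerical conventions and problem sizes

* OLS via `numpy.linalg.lstsq`; rank-deficient designs (an empty (S, E)
  cell) are rejected with the offending cell named.
* Quantiles: linear interpolation of order statistics throughout.
* SDs use ddof = 1.
* Double log-transformation is a guarded error, as is a non-positive value
  in a log-targeted biomarker.
* Test and acceptance problem sizes are chosen for desk-scale runs: unit
  tests use cohorts of ~600–4,000; parameter recovery uses 200 replicates at
  n = 10,000 (tolerance 3 Monte-Carlo SEs); bootstrap coverage uses 100
  outer replicates at n = 2,000 with B = 200 (pass band 95% ± 5 points);
  imputation recovery uses 40 replicates at n = 2,000 with 5 chained-equation
  cycles; the acceptance script runs the full pipeline at n = 6,000 with
  B = 200 and 5 cycles.

## Known limitations

* EP estimates for near-null total effects (cortisol, CRP) are intrinsically
  unstable; the `unstable` flag is a presentation aid, not a fix.
* The linear Q̄(S, G, E) model is a working model: G is a nonlinear summary
  of Σ, so strategy (a) carries a projection bias relative to strategy (b);
  on the default scenario it is small (the CDE^G test quantifies it against
  the Monte-Carlo oracle).
* Chained equations omit posterior coefficient draws, which mildly
  understates within-replicate imputation variability; the bootstrap
  dominates the interval width at the default missingness rates.
* Strategy (c) interprets "non-deprived" as the less-gendered environment by
  assumption; the package computes the contrast, not the assumption.
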