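# Methods

## Problem and scope

Short-term dietary instruments (24-h recalls) measure a person's intake on
one day, not their habitual intake.  Day-to-day within-person variation is
large — typically larger than the variation between people — so the
distribution of single-day intakes is far too wide, and the fraction of the
population below a requirement threshold computed from raw recall days is
biased, usually upward for nutrients most people nearly meet.  `dairyshift`
estimates the distribution of *usual* (long-run average) intake from two
recalls per person, applies a counterfactual diet change (raising dairy to
recommended servings), and reports survey-weighted prevalence of inadequacy
under both diets, with and without supplements.

Real survey-file ingestion (SAS transport files, food-code-to-cup-equivalent
mapping, nutrient databases) is out of scope; cohorts enter either as plain
CSV in the package dialect or from the synthetic generator.

## Measurement-error model

The amount model on consumption days is a Box-Cox-transformed linear mixed
model with a person random intercept:

g(Y_ij; λ) = β₀ + β_seq·1[recall 2] + β_wk·1[weekend] + u_i + ε_ij

* λ ∈ {0, 0.05, …, 1.0}, chosen by profile likelihood.  A fixed grid keeps
  selection deterministic and bounded; the Jacobian term (λ−1)Σ w log y makes
  likelihoods comparable across λ.
* Fitting is weighted maximum likelihood: each person's cluster
  log-likelihood is multiplied by their first-day survey weight (weights
  normalized to mean 1).  Because clusters have at most two days, the
  cluster covariance σ²_e·I + σ²_u·J inverts in closed form and the whole
  likelihood vectorizes; fixed effects are profiled out by weighted GLS and
  the two variance components are optimized by L-BFGS-B on the log scale.
  A rank-deficient design (e.g. no weekend days at all) falls back to a
  least-squares solve.
* The recall-sequence covariate absorbs the systematic Day-2 reporting
  shift; the weekend covariate absorbs the weekday/weekend intake
  difference.  Neither belongs to "usual" intake, so simulation balances
  them: sequence held at Day 1, weekend weighted 2/7.
* Zero amounts inside an "amount-only" nutrient fit are shifted by ε (half
  the smallest positive observed amount by default) before transforming;
  the shift is recorded on the fitted parameters and undone after
  back-transformation.

For episodically consumed foods (total dairy: ~16 % of generated person-days
are zero) a two-part model adds a logistic mixed model for any-consumption,
fitted by weighted ML with 25-node Gauss-Hermite quadrature over the person
random intercept.  The correlation ρ between the two person effects defaults
to 0 (uncorrelated two-part model); after the intervention every day has
dairy at or above the recommendation, the probability part degenerates to
p = 1, and estimation proceeds amount-only with a flag — the refit-both-parts
behaviour is deliberate and observable in `analysis/03_usual_intake.py`.

Nutrients (consumed near-daily) are fitted amount-only; only total dairy is
fitted two-part.

## Back-transformation and the usual-intake distribution

Usual intake on the original scale requires E_ε[g⁻¹(z + ε)].  The package
uses exact closed forms at the boundary exponents — z + 1 at λ = 1 and the
lognormal mean e^{z+σ²ₑ/2} at λ = 0 — and a second-order Taylor expansion
g⁻¹(z) + ½σ²ₑ(1−λ)(1+λz)^{1/λ−2} for interior λ, with Gauss-Hermite
quadrature available as a configuration alternative (`method="quadrature"`,
9 nodes).  The Taylor form requires g⁻¹ to exist throughout a ±3σₑ
neighbourhood; outside it the scalar API raises, while the Monte Carlo
simulation path substitutes clamped quadrature (off-domain mass treated as
zero intake) and clips final draws at 0.

The usual-intake distribution is Monte Carlo: m = 100 pseudo-persons per
participant by default (the conventional macro default; configurable), each
a fresh draw of the person random effect(s), carrying the source
participant's id and survey weight.  Everything is deterministic given the
seed, and requests beyond 10⁷ pseudo-persons are refused with guidance to
lower m.

## The intervention

Each recall day short of the age-specific recommendation (2.0 / 2.5 / 3.0
cup-eq for ages 2–3 / 4–8 / 9+) is topped up to it, and gap × composite is
added to the day's nutrients.  The gap is computed per recall day, not per
two-day mean, preserving the day-level structure the measurement-error model
needs; a `per_day=False` switch applies the participant's mean gap instead
(total added servings are identical, day-level allocation differs).  The
milk/cheese/yogurt split of added servings is not tracked: the intervention
adds a single composite, so only the total matters.  Intake above the
recommendation is never reduced.

This construction makes the cohort-mean identity
Δ(mean nutrient) = Δ(mean dairy) × composite[nutrient] hold *exactly* on raw
person-days (tested to 1e-9), and approximately after usual-intake
re-estimation.  The identity is also what ties the published
current-vs-modeled mean tables together, and the acceptance checks exploit
it: published modeled means are recomputed from published current means plus
the printed dairy change.  Because the printed dairy means carry only two
decimals, the recomputation tolerance for full-table checks is one final
printed digit plus 0.015 × composite (the propagated dairy rounding); six
benchmark cells agree within one final digit outright.

Supplements enter after estimation as a constant per-person daily shift of
the usual-intake distribution (supplement use modeled as habitual), so
food+supplement prevalence of inadequacy is never above food-only — a
monotonicity the tests verify.

## Uncertainty and significance

No single variance formula is canonical for this weighted two-stage
pipeline, so the package uses a stratified person-level bootstrap (B = 200 by default;
B = 60 in the desk-scale analysis scripts): participants are resampled with
replacement within variance strata, the *entire* estimation pipeline —
amount and probability fits, Monte Carlo distribution, prevalence — is rerun
per replicate, SE is the SD of replicate estimates and the CI the 2.5/97.5
percentiles.  Within bootstrap replicates the Box-Cox exponent is held at
the point estimate: λ selection is a discrete, slowly varying choice whose
re-selection noise would otherwise dominate small-replicate variance, and
holding it fixed keeps B full refits tractable.  Replicates that fail to
converge are dropped and counted; more than 10 % failures is an error.
Significance between current and modeled scenarios is the non-overlap of the
two 95 % CIs (touching bounds count as overlap).

## Synthetic cohorts and ground truth

The generator emulates the features of national recall data that drive the
estimator: right-skewed intakes via the same shifted-power-transform
Gaussian family the estimator assumes (an optional lognormal "misspecified"
mode supports robustness tests); within-person SD exceeding between-person
SD for every nutrient; episodic dairy via a two-part model (per-day
consumption probability ≈ 0.88 with person heterogeneity); weekend (+0.10)
and sequence (−0.05) effects on the transformed scale; lognormal survey
weights (σ = 0.5, normalized to sum to n); ~50 % supplement users with
lognormal daily amounts; and realistic exclusion-flag rates.  Default
background-intake parameters are loosely calibrated to U.S. adult intake
levels (e.g. non-dairy calcium ≈ 600 mg/d plus dairy × 298 mg/cup-eq); no
attempt is made to mimic true survey marginals nutrient-by-nutrient, nor
age/sex intake gradients — passing tests therefore demonstrate estimator
correctness under the stated generative family, not agreement with any real
population's numbers.

Ground truth comes from `true_prevalence_below`: brute-force simulation of
≥10⁶ persons whose usual intakes are computed with exact within-person
expectations (15-node Gauss-Hermite), or the Gaussian closed form when the
transform is linear and dairy contributes nothing.

## Numerical choices and conventions

* Age groups 2–3, 4–8, 9–18, 19–50, 51–70, 71+, both printed endpoints
  inclusive; age is whole years at interview; ages < 2 are out of scope.
* One-recall-day participants are accepted in estimation (their days inform
  fixed effects and between-person variance); how the original analysis
  handled them is not stated, and the ambiguity is noted here.
* EAR/AI thresholds are configuration inputs (YAML), never package
  constants; prevalence accepts per-person thresholds so sexes-combined
  strata handle sex-specific EARs correctly.
* "% below" is strict (a person exactly at the EAR is not inadequate);
  "% at/above AI" includes the boundary.
* Display rounding (servings to 0.01, percents to 0.1) is applied only in
  `*_display` outputs; full-precision CSVs are always written alongside,
  with the config hash and seed in a header comment.

## Problem sizes used in checks

Parameter-recovery checks run 20 replicates of 2,000-person cohorts;
estimator-vs-truth coverage checks run 20 replicates of 600-person cohorts
with B = 60 bootstrap replicates and m = 40 pseudo-persons; the end-to-end
bundle in `analysis/04_adequacy.py` uses 800 participants, three adult
strata, m = 50, B = 60.  These sizes are the package's own desk-scale
choices; all are configuration, not code.

## Known limitations

* The Taylor back-transformation is second-order; for heavy transforms
  (small λ, large σ²ₑ) the quadrature alternative is more accurate.
* The bootstrap treats the synthetic design as stratified simple random
  sampling with weights; it does not emulate a multi-stage cluster design.
* The two-part model's ρ = 0 default ignores any correlation between
  consumption propensity and amount; an estimated-ρ variant is left as
  future work (post-intervention dairy is consumed daily, so the choice is
  immaterial for the headline comparison).
* No isocaloric substitution: added dairy is added on top of the current
  diet, as in the modeled scenario this package reproduces.
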