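# dairyshift

**Diet-scenario modeling of dairy intake**: what would happen to the U.S.
population's micronutrient adequacy if everyone consumed the recommended
daily servings of dairy?

`dairyshift` implements, as a tested and reusable pipeline, the analysis
behind that question: it estimates **usual (long-run average) nutrient-intake
distributions** from two-day 24-h dietary recalls with an NCI-style
measurement-error model, **models the diet change** by topping each person's
dairy up to the age-specific recommended cup equivalents with a fixed
per-serving nutrient composite, and quantifies the resulting change in
**survey-weighted prevalence of inadequacy** (% below the EAR, % at/above the
AI), with and without dietary supplements.  It is written for nutritional
epidemiologists and biostatisticians who want the full chain — cohort,
measurement-error model, intervention, uncertainty — in open, testable code
driven by synthetic cohorts with known ground truth.

## The model

Daily intake of a food or nutrient on consumption days is modeled on a
Box-Cox-transformed scale as a linear mixed model,

```
g(Y_ij; λ) = β₀ + β_seq·1[recall 2] + β_wk·1[weekend] + u_i + ε_ij,
g(y; λ) = (y^λ − 1)/λ   (ln y at λ = 0),
u_i ~ N(0, σ²_u),  ε_ij ~ N(0, σ²_e),
```

with λ selected by profile likelihood on a fixed grid {0, 0.05, …, 1}.  For
episodically consumed foods (total dairy) a companion logistic mixed model
describes the probability of any consumption on a day.  All likelihoods are
weighted by first-day survey sampling weights.  The **usual intake** of
person *i* removes the within-person day-to-day noise:

```
T_i = p_i · E_ε[ g⁻¹(x'β + u_i + ε) ],
```

with nuisance covariates balanced out (sequence at Day 1, weekend weighted
2/7), estimated by Monte Carlo over pseudo-persons.  Prevalence of inadequacy
uses the **EAR cut-point method** — the weighted fraction of the usual-intake
distribution below the EAR (at/above the AI for potassium) — with standard
errors from a stratified person-level bootstrap that reruns the whole
estimation per replicate, and significance between scenarios from
non-overlapping 95 % confidence intervals.

The intervention itself is arithmetic with teeth: a recall day that is `gap`
cup-equivalents short of its age recommendation (2 / 2.5 / 3 cup-eq for ages
2–3 / 4–8 / 9+) gains `gap × composite`, where one cup equivalent of the USDA
dairy composite carries 81 kcal, 8.5 g protein, 0.87 g saturated fat, 298 mg
calcium, 20 mg magnesium, 99 RAE vitamin A, 1.55 µg vitamin D, 237 mg
potassium, and 181 mg sodium.  This forces an exact identity on cohort means
— Δ(mean nutrient) = Δ(mean dairy) × composite — which the tests verify to
1e-9 and which also pins down the published current-vs-modeled tables.

## Worked example

```bash
dairyshift simulate --n 2000 --seed 20100 --out cohort.csv
dairyshift model --recalls cohort.csv --out modeled.csv
dairyshift usual --recalls cohort.csv --nutrient calcium --out draws.csv
dairyshift adequacy --draws draws.csv --threshold 1000 --kind EAR
```

or, as a library (the numbered scripts under `analysis/` run the same steps
with narration):

```pycon
>>> from dairyshift import CohortConfig, generate_cohort, apply_exclusions
>>> from dairyshift.pipeline import fit_nutrient_distribution
>>> from dairyshift.adequacy import prevalence_below
>>> parts, days = generate_cohort(CohortConfig(n_participants=2000, seed=42))
>>> kept, removed = apply_exclusions(parts)
>>> removed
{'unreliable_recall': 34, 'lactating': 3, 'pregnant': 10}
>>> days = [d for d in days if d.participant_id in {p.id for p in kept}]
>>> dist, fit = fit_nutrient_distribution(kept, days, "calcium", m=100, seed=1)
>>> round(fit.lam, 2), round(dist.weighted_mean(), 1)
(0.65, 1154.2)
>>> round(prevalence_below(dist, 1000.0).percent, 1)
22.7
```

Here 22.7 % of the (synthetic) population has usual calcium intake below a
1000 mg EAR; the generative ground truth for this cohort configuration is
23.7 %, inside the estimator's sampling error.  After the dairy intervention
the same prevalence drops to 0.0 % — the pattern the published analysis
reports for calcium.  `analysis/04_adequacy.py` produces the full
current-vs-modeled adequacy bundle with bootstrap CIs and significance
markers; `analysis/05_published_identities.py` reproduces the published
modeled means from the printed inputs.

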