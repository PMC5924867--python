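# Methods

This note documents the statistical model behind `thaali`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Study design assumed

A fixed household triad — one pregnant woman (third trimester), one
mother-in-law, one male household head — sampled within village
clusters, each member answering up to three 24-h dietary recalls on
non-consecutive days. Members outside the triad are rejected at
validation; the pairwise ratio machinery is defined only for the three
role pairs (PW:HH, PW:MIL, MIL:HH).

## Nutrient engine

Intakes are linear in portion grams: a visit's total is
Σ portions grams/100 × per-100 g composition. No retention (cooking
loss) factors are applied; mixed dishes are expected to enter the
food-composition table as dish-level rows, produced upstream by
element-wise averaging of recipe observations (`average_recipes`).

Food-group grams are averaged over all available visits, and
"consumed any" is true if the group appears on *any* visit. The MDD-W
score counts groups consumed on **visit 1 only** (the indicator's
validation reference period); alcohol is tracked as an eleventh group
for description but never scored. Adequate diet ⇔ score ≥ 5.

## Usual intakes

Single recalls mix usual intake with large day-to-day noise, so
per-nutrient, per-role models estimate the long-run intake:

1. **Box–Cox**: λ chosen by profile maximum likelihood
   (`scipy.stats.boxcox`). Zero intakes (common for B12, eggs) are
   handled by a shift constant of half the smallest positive value,
   added before transforming and subtracted after back-transforming.
2. **Mixed model** on the transformed scale: random intercepts for
   cluster and for individual nested in cluster, fixed stratum effects
   (omitted when only one stratum is present). REML via statsmodels
   `MixedLM`; if the full fit is singular the cluster component is
   dropped first. When the within-person variance is numerically zero
   the model degenerates analytically (residual variance 0, unshrunken
   effects) instead of being fitted numerically.
3. **Usual intake** = inverse Box–Cox of
   intercept + stratum effect + cluster BLUP + individual BLUP, clamped
   at zero. The plain inverse is used — no log-normal-style bias
   correction — keeping the estimator the simple back-transformed BLUP;
   this under-states the arithmetic mean for strongly skewed nutrients,
   which is acceptable because PA and the ratio statistics are monotone
   transformations compared within the same convention.

Usual (BLUP) intakes feed the probability-of-adequacy stage. The
allocation ratios instead use plain 3-day mean intakes, the convention
for descriptive share tables; energy-adequacy ratios therefore do not
depend on the transform at all.

## Probability of adequacy

PA is the probability that a person's usual intake covers their own
requirement, taking the requirement as a random draw from their
demographic group's distribution:

* **Normal requirements** (default): PA = Φ((usual − EAR)/SD). The
  shipped EAR means/SDs per role follow WHO/FAO values for vitamin C,
  thiamin, riboflavin, niacin, B6, folate and B12, IOM values for
  calcium and for pregnant iron (23 % absorption), and IZiNCG values
  for zinc (25 % absorption women, 18 % men). Bioavailability enters
  only through these parameters; intakes are never rescaled.
* **Tabulated iron** (mother-in-law, household head): menstrual losses
  make the requirement right-skewed, so PA comes from a table of
  probabilities per intake interval. The shipped table
  (`data/iron_pa_5pct_v1.csv`) is *constructed*, not transcribed: the
  absorbed requirement is modelled log-normal (median 1.1 mg/d,
  log-SD 0.35), the dietary requirement divides by 5 % bioavailability,
  interval bounds sit at the quantiles of a 0.02-probability grid, and
  each interval carries its midpoint probability, bounding the
  discretisation error by 0.01. A Monte-Carlo integration test holds
  the table to the generating distribution within 0.02 everywhere.
  One table serves both non-pregnant roles; it is a construction whose
  parameters are editable, not a claim about any particular reference
  population.

MPA is the arithmetic mean of PA over exactly the 11 micronutrients
(energy and protein excluded); the function refuses missing or extra
nutrients rather than silently renormalising.

**Energy EARs** are kcal/kg coefficients by sex × activity level
(ICMR-derived defaults, editable CSV) times body weight, plus a flat
390 kcal/d in pregnancy.

## Allocation ratios and exclusions

All four ratio families satisfy f(a,b) = 1/f(b,a); logs are
antisymmetric, and FS:ES ≡ FS ÷ (kcalₐ/kcal_b). FS and FS:ES for a food
group exist only when *both* members consumed any of it — the household
is simply absent for that group, with no continuity correction. The
dietary-diversity analogue of FS:ES subtracts the log energy ratio from
the log score ratio rather than dividing scores by kcal. Log MPA ratios
below −8 are flagged as extreme outliers and excluded from inference;
the exclusion is one-tailed as specified, with a symmetric variant
(|log| > 8) behind a pipeline flag. A disparity classifier flags
households where one member sits below 90 % of their energy EAR while
another exceeds 110 %.

## Inference

Equity tests fit an intercept-only linear mixed model to a log ratio
with a cluster random intercept (ML, Wald 95 % CIs, α = 0.05); a
non-zero intercept is inequity. Determinant models add all hypothesised
household covariates simultaneously (reference levels: earns less than
spouse, gravidity 0, not overseas, most-disadvantaged caste group,
pre-monsoon), with household energy entering per 1000 kcal and an
optional quadratic wealth term. Collinearity is screened by VIF
(1/(1−R²) per covariate). Because within-household ratios cancel
cluster-level intake effects, the cluster variance of log ratios is
often estimated at the zero boundary; the fit then falls back to OLS,
which is the ML solution at that boundary. Percent statements use
100·(exp(c)−1) for c ≥ 0 ("higher") and 100·(1−exp(c)) for c < 0
("lower"); display rounding is half-up at one decimal and then half-up
to an integer, so values landing on x.5 at one decimal round up, which
keeps displays consistent with rounding from full-precision
coefficients.

## Synthetic-data generator

The generator is top-down so recovery tests are sharp. Each member's
true usual energy is EAR × exp(a), with log-adequacy
a = role mean + covariate effects + cluster effect + individual effect.
Role means are anchored by the household head's mean log adequacy
(default 0.13) and the configured true mean log-RDEARs (−0.20 PW:HH,
−0.15 PW:MIL), so the injected pairwise truths hold exactly whatever
body weights are drawn. Covariate effects (earnings parity by default,
+0.27 on the pregnant woman's log adequacy) are centred at their
*realised* sample means, so the marginal mean log-RDEAR equals the
configured truth in every realisation — including the all-noise-zero
case, where the estimate matches the truth to float precision. Day
intakes multiply the usual intake by exp(N(0, sd_day²)); portions are
drawn per food (role-specific daily use probabilities, log-normal
grams) and rescaled so each recall's summed energy hits the day target
exactly. Default noise: sd_cluster 0.1, sd_individual 0.2, sd_day 0.25
(log scale) — plausible magnitudes for repeated recalls, stated as
configuration rather than as estimates of any particular survey.

The optional household-calorie effect shifts the pregnant woman's log
adequacy in proportion to the centred household base energy. Since MPA
is a nonlinear downstream functional of intakes, that knob produces a
monotone, not exactly calibrated, effect on log MPA ratios; it defaults
to 0. Note also that realised household energy contains the pregnant
woman's own individual effect, so determinant models regressing on
observed household kcal see an endogenous positive association even
with the knob off — a real feature of such designs, visible in the
pipeline output.

What the generator does **not** emulate: fasting/feasting spikes,
proxy-response measurement error (the proxy flag is carried but
benign), seasonal food availability, correlated food choices beyond
role-specific group probabilities, and any systematic micronutrient
allocation separate from energy. Passing recovery tests therefore
demonstrate estimator correctness under the stated model, not
robustness to those field phenomena.

## Problem sizes and numerics

Tests and the acceptance script use the design the generator defaults
to (20 clusters × 8 households; 200 replicates for recovery/coverage,
500 for the type-I rate). Monte-Carlo agreement is judged at three
replicate standard errors; CI coverage is accepted in [90 %, 98 %] and
the type-I rate in [3 %, 7 %] at nominal 5 %. Ratio reciprocity holds
to 1e-10; the zero-noise identity to 1e-8. Mixed-model fits use
`method=["lbfgs", "powell"]` with convergence warnings suppressed and
explicit fallbacks (drop cluster component; OLS at the boundary)
instead of crashing on singular Hessians.

## Known limitations

* The usual-intake model is single-part: episodically consumed
  nutrients (B12) are handled via the shift constant, not a
  probability-of-consumption submodel, which can bias usual intakes for
  rarely eaten foods.
* Wald intervals with 20 clusters carry no small-sample
  degrees-of-freedom correction; coverage is verified by simulation
  rather than assumed.
* The iron PA table's generating parameters are a documented modelling
  choice; users matching a specific reference population should rebuild
  the table with their own median/SD via `build_iron_table`.
* No multiple-testing adjustment is applied across food groups or
  outcomes.
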