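# thaali

**Intra-household food-allocation analysis from repeated 24-hour dietary
recalls.**

In much of South Asia, food is not shared equally within a household:
pregnant women — whose requirements are elevated — often receive smaller
shares of food and nutrients than senior women or male household heads.
`thaali` (the shared meal plate) is a Python library for quantifying that
inequity from survey data. It takes repeated 24-h recall records for a
fixed household triad (pregnant woman, mother-in-law, male household
head) sampled within village clusters, and produces:

1. **Nutrient intakes** — portion grams × a food-composition table, per
   visit and averaged over the recall period, plus food-group grams and
   the minimum dietary diversity score for women (MDD-W, ≥ 5 of 10
   groups = adequate);
2. **Usual intakes** — Box–Cox-transformed intakes modelled with a
   linear mixed model (random intercepts for cluster and for individual
   nested in cluster, strata fixed), each person's usual intake read off
   the back-transformed best linear unbiased predictor (BLUP);
3. **Probability of adequacy** — for each of 11 micronutrients,
   PA = Φ((usual − EAR)/SD) against a normal requirement distribution,
   except iron in non-pregnant adults, which uses a probability table
   over intake intervals (skewed requirements, 5 % bioavailability);
   MPA is the mean PA over the 11 nutrients;
4. **Allocation ratios** between member pairs a : b —
   food shares FS = gₐ/g_b per food group;
   FS:ES = (gₐ/kcalₐ)/(g_b/kcal_b);
   RDEAR = (kcalₐ/EARₐ)/(kcal_b/EAR_b) with weight- and
   activity-based energy EARs (+390 kcal/d in pregnancy);
   and MPA ratios MPAₐ/MPA_b;
5. **Inference** — log-ratio intercepts tested against zero (perfect
   equity) with a cluster random intercept, multivariable determinant
   models (earnings parity, gravidity, empowerment, assets, household
   energy per 1000 kcal, migration, caste, season) with VIF screening,
   and conversion of log coefficients into "x % higher/lower"
   statements.

Because field datasets of this kind are rarely public, the package
includes a first-class synthetic-data generator
(`thaali.simulate`) that emulates the survey design — 20 clusters × 8
joint households, three non-consecutive recalls per member, log-normal
day-to-day noise, known variance components and known injected
allocation effects — so every stage is testable against stored ground
truth.

## Worked example

```python
from thaali import PipelineConfig, format_pct, run_pipeline

result = run_pipeline(PipelineConfig(simulation={}, seed=7, out_dir="out/demo"))
eq = result.equity.set_index(["pair", "outcome"])
row = eq.loc[("PW:HH", "log_rdear")]
print(f"{row['estimate']:+.3f} ({row['ci_low']:+.3f}, {row['ci_high']:+.3f})",
      "->", format_pct(row["estimate"]))
```

prints

```
-0.222 (-0.281, -0.163) -> 20% lower
```

meaning: across 160 synthetic households the pregnant woman's energy
intake, relative to her own requirement, averaged 20 % below the
household head's relative intake — close to the generator's configured
truth of −0.20 (18 % lower). The same run gives a positive earnings
coefficient (`+0.28`, truth `+0.27`): households where the pregnant
woman earns at least as much as her spouse allocate her a markedly
fairer energy share. Longer narrated versions of each stage are in
`examples/`; a thin CLI (`thaali simulate|pipeline|...`) wraps the same
pipeline for shell use.

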