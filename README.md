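# socbond

Social-bond strength, partner consistency, and adult female survival in
group-living animals.

In many gregarious mammals, adult females maintain differentiated
affiliative relationships ("social bonds"), and the strength and
stability of those bonds can predict fitness components such as
longevity. `socbond` implements a complete analysis pipeline for
longitudinal focal-animal observation data on such populations —
grooming and resting-proximity records, demographic tables, and decided
agonistic interactions — and links social phenotypes to mortality with
survival models. It is aimed at behavioural ecologists running (or
re-analysing) multi-year individual-based field studies.

The pipeline computes, per study year:

- **Dyadic sociality index (DSI)** for every within-group female dyad,

  `DSI_ij = 1/2 · G_ij/G_med + 1/4 · (R_ij/R_med + R_ji/R_med)`,

  where `G_ij` is the proportion of dyad observation time spent
  grooming, `R_ij`/`R_ji` are each member's focal proportions of
  resting within 1 m of the other, and the medians are taken over all
  within-group dyads across groups in the same year. A typical (median)
  dyad scores 1. Records are filtered first: focal bouts under 20 min
  are discarded, and samples are ignored for a dyad while either member
  has an infant younger than 100 days (young infants attract
  confounding social attention).
- **Bond strength**: mean DSI over a female's top *k* partners (k = 3
  or 6); **partner consistency**: prospectively over multiple years
  (fraction of top-partner "slots", `kY − k`, held by partners who
  reappear in the top *k* within two years) and retrospectively within
  years. Crossing above/below population-mean strength and consistency
  yields four **strength–consistency classes** (1 = −/−, 2 = −/+,
  3 = +/−, 4 = +/+).
- **Dominance rank** by the I&SI criterion (an ordering minimising the
  number, then the strength, of inconsistencies in the win/loss
  matrix), expressed as the proportion of groupmates outranked.
- **Survival models**: Cox proportional-hazards regressions on an age
  axis with delayed entry (left truncation at study entry or first
  birth), both fixed-time (one record per female, multi-year covariate
  averages) and time-dependent (one counting-process interval per
  subject-year), with standardized covariates, AICc model averaging of
  the class and age-at-first-birth terms across the two 3-predictor
  competition models, a quadratic group-size variant, and
  Schoenfeld-residual proportional-hazards diagnostics.
- **Node-permutation null**: class effects are also judged against a
  null built by relabelling females within each group-year's DSI matrix
  and re-running the whole downstream pipeline (top partners →
  consistency → classes → Cox fit), reporting the proportion of null
  coefficients below the observed one.
- **Repeatability (ICC)** of annual social measures from a
  random-intercept mixed model with parametric-bootstrap intervals.

Because long-term field data of this kind are rarely public, the
package ships a first-class **synthetic cohort generator**
(`socbond.simulate`) that emulates the data-generating process — latent
preferred partners with class-dependent turnover, class-dependent
mortality hazards, infants, agonism — with full ground truth, so every
stage can be validated end to end.

## Worked example

```python
import socbond as sb

tables, truth = sb.generate_cohort(sb.GeneratorParams(seed=5))
study = sb.Study(tables, sb.StudyConfig(seed=5))

res = study.fit_fixed("rank")     # class + age at first birth + rank
print(res.summary().round(3))
print(study.model_averaged().round(3))
```

This prints (class 3, strong/inconsistent, is the reference level):

```
                  coef  se(coef)  hazard_ratio  ci95_lower  ci95_upper      z      p
class_multi[1]  -1.499     0.580         0.223      -2.635      -0.362 -2.584  0.010
class_multi[2]  -1.527     0.646         0.217      -2.793      -0.261 -2.364  0.018
class_multi[4]  -1.376     0.556         0.253      -2.465      -0.287 -2.476  0.013
age_first_birth  0.084     0.216         1.088      -0.340       0.508  0.390  0.696
mean_rank       -0.019     0.208         0.981      -0.426       0.388 -0.092  0.926
```

Every strength–consistency class shows a hazard well below the
strong/inconsistent reference (hazard ratios ≈ 0.22–0.25, 95% CIs
excluding zero) — the direction of the protective contrasts this
synthetic cohort was generated with, attenuated by class-phenotyping
noise — while rank and age at first birth, which carry no effect in the
generator, stay near zero. The model-averaged table combines the rank
and group-size models by their AICc Akaike weights.

The same analysis is scriptable from the shell:

```bash
socbond simulate --seed 5 --out data/
socbond dsi --data data/ --workdir work/
socbond metrics --data data/ --workdir work/ --k 3
socbond fit --data data/ --model fixed --competition rank
socbond permtest --data data/ --n 1000 --seed 5
```

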