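# Methods

This note documents the models and procedures implemented in `socbond`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Observation model and filters

The raw material is focal-animal sampling: 30-minute bouts (possibly
truncated; bouts under `min_sample_min = 20` minutes are discarded) with
per-partner grooming and resting-within-1-m minutes. A *study year*
spans 12 months from a configurable anchor (default 1 October, matching
an autumn start of systematic observation); calendar-year anchoring is a
one-line config change. A female counts as a subject in a year when her
distinct focal-sample days exceed 10% of the days in that year — the
presence rule is stated in terms of "being a subject for >10% of the
year", and days-with-any-sample is our operationalisation of it.

Mothers of young infants attract extra social attention, so a sample is
excluded *for a dyad* while either member has an infant younger than
100 days (days 0–99 after the birth excluded, day 100 retained). Because
the exclusion depends on the partner, dyad observation time `T_dyad` is
dyad-specific: the sum of both members' focal minutes valid for that
dyad.

## Dyadic sociality index

For dyad (i, j) in a year:

- `G_ij` = grooming minutes between i and j, pooled over direction and
  over which member was focal, divided by `T_dyad`;
- `R_ij` = i's valid focal minutes resting within 1 m of j divided by
  i's valid focal minutes (and `R_ji` symmetrically). Resting proximity
  is kept directional because focal protocols score it asymmetrically.

`DSI = 1/2·G/G_med + 1/4·(R_ij/R_med + R_ji/R_med)`, with `G_med` the
median of `G_ij` over all within-group dyads pooled across groups in
the year and `R_med` the median of the pooled directional components
{R_ij, R_ji}. Observed-but-zero-affiliation dyads count toward the
medians; dyads with `T_dyad = 0` are omitted entirely. A zero median
raises an error: a population sparse enough for that is incompatible
with a median-normalised index, and silently substituting another
normaliser would change the estimand.

A Mantel-style node-permutation correlation between the grooming and
proximity matrices of a group-year is provided
(`dsi.matrix_correlation`) as a descriptive check that the two
affiliation channels co-vary; it is a utility, not part of the survival
analysis.

## Partner metrics and classes

Top-k partners (k = 3 default, 6 as alternative) are ranked by DSI with
deterministic ties (descending DSI, then ascending partner id). Bond
strength is the mean DSI over the top k.

Multi-year consistency is *prospective*: a top partner in year t is
consistent if she re-enters the top k in year t+1 or t+2 (penultimate
year: t+1 only); the score is consistent slots over total assessable
slots (`kY − k` when every year has k partners; years with fewer
coresident females contribute their actual slot counts). Annual
consistency is *retrospective*: the fraction of this year's top k
present in the top k of either of the two preceding observed years
(second year: the previous year alone); it is undefined in a female's
first year, which is why time-dependent analyses use fewer subject-years
than exist. Both directions share one enumeration core and are verified
against a literal brute-force restatement of the rule.

Classes cross above/below the population *mean* of strength and of
consistency (1 = −/−, 2 = −/+, 3 = +/−, 4 = +/+). A value exactly at
the mean falls on the "−" side; the choice is arbitrary but fixed and
logged. Partner changes (a top partner absent from the next observed
year's list) can be attributed to the partner's death when her death
falls in the intervening window; the per-female death-attributed
proportion is undefined for females with no changes.

## Dominance

Win/loss matrices per group-year come from decided agonistic
interactions. The I&SI ordering minimises the number of inconsistencies
I (dyads whose lower-ranked member won more) and then their summed rank
distances SI. The search is a local-search heuristic (all pairwise
swaps plus single-element relocations, 12 seeded random restarts);
on rosters of ≤ 8 it is checked against exhaustive search in the test
suite. Unknown (zero-interaction) dyads contribute neither I nor SI; an
all-zero matrix returns the roster order flagged uninformative. Rank is
reported as the proportion of groupmates outranked ((n − position)/(n −
1)), averaged over years for multi-year analyses.

## Survival models

Survival runs on the **age** axis with delayed entry: a female enters
the risk set at her age when systematic observation began (study start
if she was adult then, otherwise her age at first birth) and leaves at
death or censoring. Ages are whole-day differences divided by 365.25.

The partial likelihood is maximised by Newton–Raphson in
`socbond._cox`, written in-house so the permutation null can refit the
model tens of thousands of times within practical runtime. Risk sets
are {i : entry_i < t ≤ stop_i}, ties use the Efron correction, and the
same solver serves both the fixed-time fit (one row per female) and the
time-dependent fit (one (start, stop] row per subject-year, event on
the terminal interval of a death). The solver is validated against
lifelines' `CoxPHFitter` (with `entry_col`) and `CoxTimeVaryingFitter`
to ~1e-4, and diverging coefficients (|β| > 15, in practice a class
dummy with no events) raise a separation error rather than returning a
junk estimate.

Numeric covariates are standardized (mean 0, sample-sd 1 over the
analysis units); classes enter as dummies against reference class 3
(strong/inconsistent), so each reported coefficient is a direct
contrast with the high-risk stratum. Confidence intervals are Wald,
β ± 1.96·se; hazard ratios are exp(β). The two fixed-time models each
carry three predictors — class, age at first birth, and one
social-competition covariate (dominance rank or number of adult female
groupmates) — keeping roughly 5–10 events per variable at realistic
death counts; the class and age terms are combined across the two
models by AICc model averaging (Akaike weights, unconditional standard
errors with the between-model variance component). AICc uses the number
of events as the effective sample size, the common small-sample
convention for Cox models. A quadratic group-size model (z-scored group
size and its square alongside class and age at first birth) probes for
an intermediate-optimum group size.

Proportional hazards are checked by correlating Schoenfeld residuals
with transformed event time (default 1 − KM(t⁻), computed from the
model's own risk sets so delayed entry is respected). The per-term and
global chi-squares use the Grambsch–Therneau average-information
approximation; against R `survival::cox.zph` they agree to within a few
percent, which is adequate for a diagnostic whose output is a p-value
compared to 0.05/0.10.

## Node-permutation null

Because class membership derives from dyadic data, class effects are
additionally referenced to a network null: in each replicate, every
group-year's roster labels are permuted uniformly and independently
(dyadic values conserved, identities moved — any female could occupy
any network position), the top-k/strength/consistency/class pipeline is
recomputed, and the fixed-time model is refitted with the non-network
covariates (rank, group size, age at first birth) untouched. The
summary per class contrast is the one-sided proportion of null
coefficients below the observed one. Class thresholds are recomputed
from each permuted sample by default (full-pipeline null); a
fixed-threshold variant is exposed by flag. Replicate seeds are spawned
from a master seed, making the full null distribution bit-reproducible.
Null refits that fail (separation from an empty class) are dropped and
counted; results with > 20% failures are flagged unreliable.

## Repeatability

Repeatability of annual measures (bond strength, rank, group size) is
the intraclass correlation from a Gaussian random-intercept mixed model
fitted by REML: R = σ²_between / (σ²_between + σ²_residual), with group
size and year index as default fixed effects (configurable). The 95% CI
is a parametric bootstrap (simulate from the fitted model, refit,
percentiles). Singular fits (between-variance at the boundary) return
R = 0 with a flag.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline targets: 8
social groups of 3–21 adult females, up to 8 study years, 67 ± 20 focal
hours per subject-year, staggered adult entry (≈15% of females reach
first birth during the study), interbirth intervals of ≈2.5 years so
the infant filter removes a realistic share of samples, and ~4 decided
agonistic interactions per dyad-year with a 10% upset rate against a
latent linear order.

Each female carries a latent class built from two independent axes:

- **Strength**: strong females place larger additive boosts on their
  preferred dyads (multiplier 8 vs 4) and spend more of their focal
  time affiliating (rate factors 1.6 vs 0.75 on the typical 5% grooming
  / 10% resting time budgets).
- **Consistency**: each female keeps a set of ~3 preferred partners;
  a bond persists from year to year only while *both* members are
  stable (pair breakup probability = max of the two members' turnover
  rates: 0.08 for consistent, 0.55 for inconsistent types). New bonds
  favour mutual and like-typed partners (weights 6 and 4) and avoid the
  chooser's previous two years of partners, so broken bonds do not
  reform by chance from small pools.

The casual background affinity of every dyad is redrawn each year from
a Gamma distribution, so only preferred bonds persist. Behaviour is
generated at the per-sample level (zero-inflated Gamma totals allocated
to one affinity-weighted partner per bout), which is what gives the
minimum-duration and infant filters real bite. Mortality is exponential
from adult entry with per-class hazards
`baseline_hazard · exp(class_log_hr[class])`; the defaults put class 3
(strong/inconsistent) at the highest risk with contrasts −2.1 / −1.5 /
−3.0 for classes 1/2/4 and a baseline of 0.18/yr, chosen so the
marginal death rate is ≈0.046 per subject-year (≈20 deaths per 437
subject-years). Administrative censoring falls at the study end.

Under the defaults the measured phenotypes land near the emulated
study's descriptives: mean top-3 bond strength ≈ 6–7.5 × the median
dyad (study: 7.6 ± 2.5), multi-year consistency ≈ 0.65–0.75 (study:
0.51 ± 0.18 — measured consistency runs somewhat high here because the
two-year reappearance window forgives single-year absences more often
in mid-sized groups), and measured classes agree with latent classes
for roughly 60–80% of females. That last number matters for
interpreting validation results: effects are attached to *latent*
classes, so pipeline-level estimates are attenuated by misclassification
exactly as field estimates would be by phenotyping noise.

## Validation scenarios and problem sizes

`socbond.scenarios` pins three designs used by the validation suite:

- **recovery**: direct survival simulation, n = 1,000 females, balanced
  classes, true class-4 log HR −3.0. Over 300 replicates the fixed-time
  fit's mean bias is < 0.03 and 95% CI coverage ≈ 0.95–0.96.
- **null_calibration**: 200 small replicate studies (5 groups of 6–9,
  5 years, 32 ± 8 focal hours) with zero class contrasts, 200
  permutations each; the one-sided permutation proportion is uniform
  (Kolmogorov–Smirnov). Small studies keep the 200-replicate design
  affordable; uniformity under the null is scale-free, so nothing is
  lost by shrinking.
- **strong_effect**: 16 study-scale replicates (8 groups of 9–13, 8
  years, all adult at entry) with sharply separated latent classes and
  a −3.0 class-4 contrast; the median one-sided proportion is ≈ 0.02.
  The sharp separation (zero vs total turnover, strong assortative and
  mutual bonding) is deliberate: this scenario demonstrates *power* of
  the permutation machinery, and entangling it with phenotyping noise
  would test the generator's misclassification rate instead. Replicates
  whose observed fit separates (a zero-event class, i.e. an infinitely
  protective observed contrast) are excluded, which can only make the
  check harder to pass.

## Numerical choices and degenerate inputs

- Tie-breaks: top-k by (DSI desc, id asc); class boundary at the mean
  goes to "−"; I&SI restarts and the permutation engine are seeded.
- Newton convergence: gradient sup-norm < 1e-9 with step-halving;
  covariates centred internally (cancels in the partial likelihood).
- Degenerate inputs raise rather than guess: no events, overlapping
  intervals (naming the subject), zero-variance covariates (naming the
  covariate), zero annual medians, rosters of 1 for rank, a single
  observed year for multi-year consistency.
- Dates are whole days throughout; `DAYS_PER_YEAR = 365.25`.

## Limitations

- The generator does not model group fission, male behaviour,
  seasonality, kinship structure, or immigration; inference about those
  processes is out of scope.
- Passing recovery tests on synthetic cohorts shows the pipeline is
  consistent with its own data-generating assumptions (exponential
  per-class hazards, stable group membership, honest filters); it
  cannot certify behaviour under field pathologies such as observer
  drift or unmodelled confounding between group size and observability.
- Females observed in fewer than two subject-years are excluded from
  multi-year analyses (consistency needs ≥ 2 years). Subjects must
  therefore survive ≈ 2 years after entry to be analysed, a selection
  the fixed-time models share with the study design they mirror; at the
  high mortality rates of some validation scenarios it visibly
  attenuates class contrasts.
- The proportional-hazards diagnostic uses the average-information
  approximation and aggregates tied events per event time; with heavy
  ties its statistic can drift a few percent from R's exact solve.
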