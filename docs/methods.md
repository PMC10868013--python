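# Methods

## Scope and data model

The pipeline quantifies the association between area-level socioeconomic
deprivation and premature mortality, defined as death between ages 1 and 74
in completed years. Age 0 is excluded throughout (infant mortality is
driven by distinct mechanisms and is incompletely captured in
register-based sources); ages 75+ are excluded because cause-of-death
certification deteriorates with competing morbidity at high ages.

Inputs are individual death records (age, sex, calendar year, area of
residence, ICD-10 underlying cause), mid-year population counts per
area × sex × single-year age × year, and one deprivation score per area per
index vintage. Person-years of exposure for a period are the sum of
mid-year counts over the period's years. The default calendar layout maps
1998–2003 and 2004–2008 to the 2001 index vintage and 2009–2013 and
2014–2019 to the 2011 vintage.

## Deprivation deciles

Areas with 10 or fewer inhabitants (per vintage) are excluded — their rates
are statistically unusable and their identifiability raises privacy
concerns. Remaining areas are ranked by deprivation score, highest
deprivation first, and cut into ten equal-count deciles; decile 1 is the
most deprived and decile 10, the least deprived, serves as the
counterfactual reference everywhere. Two conventions are deliberate,
documented choices where no canonical rule exists: score ties break by
area id (making the assignment invariant to input order), and when the
area count is not a multiple of ten the remainder goes to the
lowest-numbered deciles. Deciles are equal-count by *area*, not
population-weighted: the index is built and ranked at area level and area
populations are heterogeneous by design. Deaths and exposure in excluded
areas are dropped but counted; rows referencing unknown areas are routed to
an "unassigned" report, never silently dropped, and a conservation check
(in + excluded + unassigned = total) is logged per run.

## Cause grouping

Causes are grouped on the normalized 3-character ICD-10 category in a
three-level hierarchy: chapter (e.g. I00–I99), configurable code-range
subcategory (e.g. I20–I25), and single 3-digit diagnosis (e.g. I21).
A subcategory or diagnosis becomes a node only if it accounts for strictly
more than 1,000 deaths pooled over both sexes, all deciles and the full
study window — a pragmatic floor that keeps cause-specific rates stable.
The threshold is applied pooled (not per sex) because the gating is about
count stability, not reporting granularity; raising it can only remove
nodes (monotonicity, property-tested). A range that is a single code
(e.g. C50) is its own diagnosis and is not duplicated as a level-3 child.
Codes outside the chapter table (U-codes and malformed residue survive in
real registries) go to an "unclassified" bucket with a warning; deaths in
codes with no retained subcategory still count at chapter level.

## Standardization and contrasts

Directly standardized rates use 5-year age groups with 1–4 as the first
group. The shipped default standard is the 2013 European Standard
Population restricted to ages 1–74, with the 1–4 weight set to 4/5 of the
0–4 weight (4,000 of 5,000); the standard is ordinary configuration and any
positive contiguous weight set can be substituted. Variance uses the
conventional Poisson form for a directly standardized rate,
`Var = 10^10 · Σ w_a² d_a / n_a² / (Σ w_a)²`, with a normal 95% interval
floored at zero. Rate-ratio intervals use the log-normal approximation
`se(log RR) = sqrt(V1/r1² + V2/r2²)`; the difference of two standardized
rates is tested with `z = (r1 − r2)/sqrt(V1 + V2)`. These are the standard
textbook conventions; where a published table provides only a point
estimate and CI, `StandardizedRate.from_interval` back-derives the variance
from the interval half-width, which is exact under the same normal
approximation. An age group with exposure but no deaths contributes rate 0
at full weight; exposure-free groups with deaths are an error.

## Attributable fraction

Expected deaths in each stratum apply the reference decile's
age-sex-period(-cause) rate to the stratum's person-years; attributable
deaths are observed − expected and `PAF = 1 − Σexpected/Σobserved`. By
construction the reference decile's attributable count is exactly zero, and
the per-decile attributable counts sum exactly to the total — in the point
estimate and in every Monte-Carlo iteration (property-tested).

The 95% uncertainty interval is a parametric bootstrap: each of 10,000
iterations redraws every stratum's death count from Poisson(observed
count), recomputes the reference rates *from the draw* (the reference
decile is resampled too — its simulated rates define that iteration's
counterfactual), and re-derives the PAF; the UI is the percentile band of
the simulated PAFs, not a normal approximation. Resampling is age-stratified
by default, consistent with the rest of the analysis; a
`age_stratified=False` flag collapses ages before drawing for users who
want sampling at sex × period × decile × cause resolution only — the point
estimate is unchanged and interval widths are close. Strata are processed
in a fixed sorted order under one seeded generator, so results are
bit-identical across runs and machines. Iterations with zero total
simulated deaths (possible only in tiny scopes) are recorded as missing and
warned about above 1%.

## Years of life lost

Crude PYLL sums `75 − x` over deaths at completed age x — the uncorrected
count for actual deaths, not a standard-population construct. An optional
mid-year convention (`75 − (x + 0.5)`) is available behind a flag but is
not the default. "PYLL due to inequality" is the counterfactual
decomposition: expected deaths per single-year age under reference rates,
converted to expected PYLL, with excess = observed − expected; this — not a
naive subtraction of the reference decile's own PYLL total — is the reading
under which the national observed/expected/excess figures decompose
exactly, and the identity observed = expected + excess holds at every
aggregation level by construction. Age-standardized PYLL per 100,000
persons uses the same standard and contrast conventions as the rates.

## Synthetic registry

The generator emulates the registry structure the analysis assumes, at
configurable scale. Defaults are the full-scale study conditions:

- **Areas**: 18,000 areas, populations lognormal(μ=5.84, σ=1.30) — median
  ≈344, quartiles ≈133/759, matching the heterogeneity of Belgian
  statistical sectors. Each area's deprivation score is its latent risk
  percentile, so ranking scores recovers the programmed risk ordering.
- **Baseline mortality**: age-sex schedules for the least deprived decile
  calibrated to land near 490 (men) / 245 (women) per 100,000
  age-standardized — late-1990s western-European premature mortality.
- **Gradient**: decile risk multipliers log-linear between `target_rr`
  (default 2.0) at decile 1 and 1.0 at decile 10, applied to all ages and
  both sexes.
- **Trends**: multiplicative annual declines of 1.8% (most deprived) and
  2.8% (least deprived), log-linearly interpolated between, so relative
  inequality widens over 1998–2019 as observed in European registries.
- **Causes**: ~13 ICD-10 categories with decile-specific tilts (COPD and
  alcoholic liver disease strongly deprivation-linked, breast cancer flat);
  tilts reweight the cause mix within a decile without altering all-cause
  rates.
- **Counts**: deaths Poisson per area × sex × single-year age × year;
  populations constant over calendar time.

Truth deciles are assigned by the same exclusion-and-ranking routine the
analysis uses, so the `SyntheticTruth` object's analytic PAF and
standardized-rate ratios refer to exactly the decile partition the pipeline
recovers; excluded tiny areas generate deaths at reference risk, which the
analysis then drops. Note the analytic all-years ratio exceeds `target_rr`
slightly (≈2.2 at default settings) because differential decline compounds
over the pooled window — recovery tests compare against the analytic value,
not the nominal input.

Deliberately not simulated: migration and internal mobility, longitudinal
exposure histories, sex- or age-specific cause schedules, realistic
national age pyramids (ages are uniform within 1–74), and score drift
between index vintages. Passing recovery tests therefore demonstrates that
the estimators are consistent and calibrated under the model's own
assumptions — not that those assumptions hold in any real registry.

## Problem sizes in the test suite

The suite exercises reduced configurations chosen to keep runs quick while
leaving all statistical checks meaningful: parameter-recovery of the rate
ratio runs one 2,000-area registry over the full 1998–2019 span; PAF-UI
coverage runs 100 replicate generations at 400 areas over a single
1998–2003 period with 2,000 Monte-Carlo iterations each (the coverage
property is scale-free); determinism and stability checks run on fixed
two-decile toys at 10,000 vs 100,000 iterations. The acceptance script uses
the 2,000-area full-span configuration.

## Known limitations

- Area-level association only: no individual-level inference (ecological
  fallacy applies), no confounding adjustment beyond age, sex and period.
- The variance and CI conventions above are the standard choices but not
  the only ones; bootstrap-based rate intervals would differ slightly at
  very small counts.
- The Poisson Monte Carlo conditions on observed person-years; population
  uncertainty is not propagated.
- Cause-specific PAF/PYLL inherit whatever certification error is in the
  underlying cause coding; no garbage-code redistribution is attempted.
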