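# Methods

## Problem and scope

A brand-level food-consumption survey records eating occasions against an
*extensive* list of food codes, each with a per-100 g composition record. To
build a usable recall instrument, similar codes are merged into a *concise*
list of generic codes. This package implements the derivation of the concise
list, the recomputation of per-participant nutrient intakes under both lists,
and the statistical comparison of the two sets of estimates. It does not
model usual-intake (within-person) variance, recipe disaggregation, retention
factors, or the semantic judgement of which items are "similar": the food
type assignment is an input column, because that judgement is expert-made and
not algorithmically reproducible.

## Compression rule

Codes with `is_supplement = True` or `exception_class ≠ none` map to
themselves and keep their composition. All remaining codes in a food type map
to one generic code whose composition is copied bitwise from the
*representative*: the member with the most eating occasions (one event row =
one occasion; grams are irrelevant), ties broken by smallest `code_id`. A
type with a single mergeable code keeps its own id, which makes the
derivation idempotent: run on an already-concise register it returns the
identity mapping. A type with zero recorded occasions falls back to the tie
rule with a logged warning. Rare/unusual exception flags can be suggested
from an occasions-below-threshold screen, but flags are never applied
silently — they are an input.

Consequences used as test invariants: every concise composition record equals
some extensive record exactly; the image size is
(#types with ≥ 1 mergeable code) + #exceptions + #supplements; and at zero
within-type composition heterogeneity the recomputed intakes are bitwise
identical under both lists.

## Intake engine

Mean daily intake divides the record-window total by `recorded_days`
(default 4) regardless of zero-consumption days, the standard food-record
convention. The `food_only` scope drops supplement-coded events; the
`all_sources` scope keeps them, so all-sources intakes dominate food-only
intakes elementwise. Percent energy uses kJ/g conversion factors
(UK convention: protein 17, fat 37, available carbohydrate 16, alcohol 29;
fat sub-fractions use the fat factor), configurable because composition
tables differ by country. Energy under-reporting is screened once, on the
extensive-list all-sources energy, as EI:BMR strictly below 1.1 with BMR
from the adult Schofield (1985) coefficients shipped as package data
(`src/foodlist/data/schofield.tsv`; half-open age bands 18–30, 30–60, 60+).
The same exclusion set serves both lists' EAR analyses.

## Agreement statistics

* **Percent difference** `100·(mean_new − mean_old)/mean_old`; undefined
  (reported missing) when the old mean is zero.
* **Test selection.** Transformations are tried in the fixed order
  none → ln (all values > 0) → √ (all ≥ 0). The first under which *both*
  vectors pass a Lilliefors-corrected KS normality test
  (`statsmodels.stats.diagnostic.lilliefors`) at α = 0.01 selects a paired
  *t* test on the transformed values; otherwise a Wilcoxon signed-rank test
  runs on the raw values. Identical vectors report p = 1 with a warning.
  The fixed order and the Lilliefors correction are design choices made for
  determinism; which nutrients get which transform is data-dependent.
* **Effect size.** Primary convention is the pooled-SD d
  (`(mean_new − mean_old)/√((sd_old² + sd_new²)/2)`); d_z
  (mean difference / SD of differences) is also emitted because the paired
  convention is genuinely ambiguous in the field.
* **Tertiles.** Sort by (value, participant_id); class sizes as equal as
  possible with earlier classes taking the remainder (n = 10 → 4/3/3). The
  id in the sort key makes tie handling deterministic. Tertiles are computed
  within each list's own distribution.
* **Cohen's κ** is unweighted, κ = (p_o − p_e)/(1 − p_e) with p_e from
  marginal products; when both classifications are constant and equal
  (p_e = 1) κ is 1 by convention, logged.
* **EAR cut-point / UL.** Prevalence of inadequacy is the fraction of
  retained participants with all-sources intake strictly below the sex–age
  stratum EAR (under-reporters excluded); UL exceedance is strictly above,
  with no under-reporter exclusion. Both boundaries are config-overridable
  (`ear_strict_below`, `ul_strict_above`). Participants without a stratum
  value are excluded per nutrient, logged.

## Synthetic-data generator

The generator states a world at reduced scale: 300 participants, 20 food
groups × 2 types × 8 brands (320 food codes) plus 10 supplement codes, 4-day
records, Poisson(5)+1 occasions/day, lognormal portions (µ = 5.2, σ = 0.6,
median ≈ 180 g — chosen so daily energy lands near 9–10 MJ for adults and the
EI:BMR screen flags a small, plausible fraction rather than most of the
sample), Zipf(s = 1) brand popularity over a fixed per-type ranking
(market-share-like skew), 5 % exception codes in a 48:62:3 class mix, 25 %
supplement users. Each food type has a latent base profile over a 35-nutrient
panel with energy built from the macronutrients via the UK factors; each
brand's composition is the base times exp(ε), ε ~ N(0, σ²) iid per nutrient —
multiplicative so nutrients stay positive and the dial is scale-free across
nutrients spanning orders of magnitude. Supplements carry micronutrients only
(lognormal, high density) and zero energy, emulating multivitamin-style
preparations.

The amount/occasion distributions are placeholders for structure, not
calibrated to any national survey: the generator emulates nesting, skew and
panel shape, not real food composition, seasonal or day-of-week effects, or
under-reporting *behaviour* (our under-reporter fraction arises from honest
simulation tails, not misreporting). A green test therefore establishes that
the procedure is implemented correctly and behaves as theory predicts in σ,
not that any particular real-survey agreement level is reproduced.

The DRV generator places EAR at the 25th and UL at the 90th percentile of the
simulated all-sources intake distribution within each sex × age-band stratum
(18–65, 65+), and calibrates macronutrient rule thresholds from the simulated
%E / absolute / per-kg distributions, so every classification table is
non-degenerate by construction. `default_macro_rules()` provides the real
EFSA/UK reference values (protein ≥ 0.83 g/kg/d, carbohydrate 45–60 %E, fat
20–35 %E, saturated fat ≤ 10 %E inclusive, fibre ≥ 25 g/d) for use with real
data.

## Numerical and design choices

* TSV, UTF-8, header row; composition and event amounts written at full
  precision (`%.17g`) so write→read round-trips exactly; report tables are
  the rounded surface (percentages 1 decimal, κ/d/ρ 3 decimals).
* The run manifest contains only deterministic content (config snapshot,
  seed, input/output SHA-256 hashes, version); wall-clock timings go to
  `run.log` so identical inputs give byte-identical manifests.
* All randomness flows from one `numpy` Generator seeded by the design seed;
  identical (design, config, seed) reproduce every table byte-for-byte.
* Significance level α = 0.01 throughout, chosen low in lieu of a formal
  multiple-testing correction across the ~35 nutrients.

## Known limitations

Lilliefors p-values from the statsmodels table method are bounded away from
0/1, which only matters at the screening threshold, not for the paired-test
p-values reported. The frequency rule counts occasions over all rows, not
distinct consumers — with highly clustered consumption these can disagree.
κ is unweighted; adjacent-tertile confusions count the same as extreme ones.
At very small strata the quantile-calibrated DRVs are noisy; the generator
logs stratum sizes through the standard validation path.
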