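# foodlist

Tools for **compressing a brand-level dietary-survey food list into a concise
generic list** and for quantifying what that compression does to nutrient
intake estimates.

Brand-level national nutrition surveys code thousands of food items, each with
its own composition record. Self-administered recall tools cannot present
users with thousands of entries, so similar items must share one generic code
and one composition record. The question this package answers for a given
survey (or a simulated one) is: *how much do population intake estimates and
individual-level classifications change when the extensive list is replaced by
the concise one?*

It is aimed at nutrition-survey methodologists building recall instruments and
at anyone validating a short food list or FFQ against a reference method.

## Method

**Compression.** Food codes are nested in food types, which are nested in food
groups. Within each food type, every ordinary brand code is recoded to one
generic code whose composition is copied from the *most frequently consumed*
member code (frequency = number of eating occasions; ties break to the
smallest code id). Nutritional supplements and flagged exception codes
(recipe ingredients, rarely consumed unusual items, items unique to one
participant) keep their original code and composition.

**Intake recomputation.** Mean daily intake per participant and nutrient is
`Σ amount_g/100 × composition(code) / recorded_days`, computed under both
lists, from food sources only and from all sources (supplements included).

**Agreement.** Per nutrient: the percent difference of means
`100·(x̄_new − x̄_old)/x̄_old`; a paired *t* test on a normalising transform
(none → ln → √, chosen by a Lilliefors-corrected Kolmogorov–Smirnov screen at
α = 0.01) or a Wilcoxon signed-rank test when nothing normalises; Cohen's
*d* = (x̄_new − x̄_old)/s_pooled (and d_z); Spearman's r_s; tertile
cross-classification with unweighted Cohen's κ = (p_o − p_e)/(1 − p_e).
Individual classification against dietary reference values: macronutrient
rules (%E maxima/ranges, absolute and per-kg minima), prevalence of
inadequacy by the EAR cut-point method (participants with EI:BMR < 1.1
excluded, BMR from the Schofield equations) and UL exceedance.

**Synthetic surveys.** A seeded generator emulates the survey structure
(brands in types in groups, Zipf-skewed brand popularity, lognormal portion
sizes, multi-day records, ~35-nutrient panel, separately coded supplements).
One dial, `heterogeneity_sigma`, sets the SD of per-brand log-multiplicative
composition noise within a food type — at σ = 0 compression is provably
lossless, and agreement degrades as σ grows.

## Worked example

```sh
foodlist demo --seed 7 --out run/
```

runs simulate → compress → intake recomputation → concordance on a default
synthetic survey (300 participants, 20 food groups × 2 types × 8 brands,
σ = 0.15) and prints:

```
food codes: 330 -> 66 (80% reduction)
nutrients evaluated: 35
mean |% difference|: 1.86
max |Cohen's d|: 0.209
Spearman rho range: 0.977-0.994
same tertile: 88.0-95.3%
tertile kappa: 0.820-0.930
```

Read: collapsing 330 brand codes to 66 generic codes moves population mean
intakes by under 2 % on average, leaves individual rankings nearly intact
(r_s ≈ 0.98), and keeps ~9 in 10 participants in the same tertile of every
nutrient's distribution — the regime in which a concise list is fit for use.
`run/report/` holds the full TSV tables (nutrient_stats, tertile_agreement,
drv_macros, ear, ul, reduction), a deterministic `manifest.json` and a
`run.log` with exclusion tallies.

The same stages are available separately (`foodlist simulate|compress|
intakes|concord|report`) and as library functions (`gen_bundle`,
`compress_bundle`, `compute_daily_intakes`, `run_concordance`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the complete pipeline from scratch on the seeded default design and
verifies that every report table is produced, then writes the results JSON.

See `docs/methods.md` for modelling assumptions, parameter defaults and known
limitations.
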