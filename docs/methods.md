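# Methods

## The surveillance problem

Large out-of-home (OOH) food chains publish energy and nutrient values for
their menu items online, each in its own format. Turning those
publications into a longitudinal database involves four stages, and this
package implements each as a tested module:

1. **Inclusion** (`filters`): which businesses, chains and documents enter
   a quarterly collection wave;
2. **Harmonization** (`standardize`): mapping heterogeneous headers and
   cell text onto one canonical schema;
3. **Analysis** (`analysis`): per-meal / daily reference-intake exceedance
   and item-level availability statistics;
4. **Synthesis** (`synthetic`): a generator that emulates the source
   heterogeneity with exact ground truth, standing in for scraped data.

## Inclusion model

Two sampling frames: businesses with ≥ 250 employees (the population a UK
calorie-labelling policy covers), supplemented by the top-100 restaurants
by sales volume. Within an included business each chain (brand) is kept
iff it publishes nutrition information online; franchise operators are
dropped unless their franchisor's chain is not otherwise captured, since
franchisees serve the franchisor's menu. Per chain, the main menu plus
children's and promotional menus are used, at the first listed London
location (or a seeded-random location, held fixed across waves). A
nutrition document more than 3 calendar years older than the wave date is
invalid; exactly 3 years is still valid (strict reading of "more than"),
and documents without a timestamp are retained since their age cannot be
established. All "promotional" menus are treated as relevant — the data
carries no signal to judge relevance further. Every decision emits one
machine-readable reason code; per-stage counts satisfy
`in = out + Σ exclusions`.

## Harmonization rules

* **Headers** are normalized (case-fold, trim, collapse whitespace,
  underscores→spaces), checked against a many-to-one synonym map, with a
  trailing unit parenthetical stripped only as a fallback so "Energy (kJ)"
  can route to the kJ field. A per-100g marker is detected first and
  re-attached as a suffix. The shipped map covers the dialects the
  generator emits plus the canonical master columns (making harmonization
  idempotent); it is a YAML file users can extend. Unmapped headers are
  reported, never silently dropped.
* **Values**: `"<x"`/`">x"` keep `x` with an operator flag (conservative
  substitution); dash or blank is missing; thousands separators and
  trailing unit tokens are accepted. Verbatim text is preserved through to
  the master table (`verbatim_*` columns).
* **Energy** is resolved to kcal, preferring kcal, converting kJ at
  4.184 kJ/kcal, and warning when both units are present but disagree by
  more than 2 kcal (beyond mutual rounding error).
* **Serving weight**: stated, else derived as the median of
  `100 × per-serving / per-100g` over nutrients with both values (energy
  participates like any nutrient). Candidates require a per-serving value
  ≥ 2 (g or kcal): menus print one decimal, so smaller values give
  candidates with up to ±50% error that would trip the consistency gate
  at random. The gate rejects the panel when max/min − 1 > 0.15. With a
  stated weight, a per-100g-only panel also yields per-serving values
  (`per-100g × weight / 100`).
* **Pizza portions**: items of pizza chains in a pizza menu section are
  normalized by size keyword — large / family / for sharing / medium to
  exactly 3 slices, small / individual to the whole pizza (the convention
  of the leading UK pizza chain). The source basis per size class (per
  slice or per whole, with a configurable slice count, default 8) lives in
  `data/pizza.yaml`; a pizza item with no recognized keyword is an error,
  and original values are always retained. Whether a "medium" with fewer
  than 3 slices should behave differently is not determinable from the
  sources; the size→basis map is the single point of configuration.
* **Compilation**: one master CSV per wave, fixed column order, one row
  per item record; duplicate (chain, item-name) keys are rejected — size
  and customization variants must already carry distinct descriptors.
  Re-standardizing a master reproduces every value column; provenance
  columns describe the new pass (a master *states* its weight, so a
  previously derived weight becomes "stated").

## Exceedance statistics

Daily reference intakes (UK adult): 2000 kcal, 70 g fat, 20 g saturated
fat, 260 g carbohydrate, 90 g sugars, 6 g salt. Per-meal thresholds:
600 kcal for energy (the configured meal recommendation, not 30% of daily
energy — they coincide at defaults) and 30% of daily for the rest.
"Exceeds" is strictly `>`: the recommendations are upper bounds, so
equality complies. Items missing a nutrient leave that nutrient's
denominator. Pooled summaries concatenate wave masters, so an item
appearing in four waves contributes four records and pooled denominators
are exactly the sums of wave-level ones. Operator-substituted values are
compared like any other value. Percentages are rounded half-away-from-zero
to one decimal. Protein and fiber have no reference values and appear only
in availability. Availability is quoted on the energy-reporting base per
wave; serving-weight availability counts stated and derived weights.

## The synthetic generator

Defaults encode the study conditions the package is sized for: 85 chains
with data across the four 2021 quarterly waves; 150–300 items per chain
per wave (≈ 76,000 records in total); a frame of 1043 large businesses of
which 256 report online, 196 of those as franchisees with 3 retained for
uncaptured franchisors, plus 3 chains from the top-100 sales frame; one
extra chain with a stale (4-year-old) document that the document filter
removes.

* **Values.** Each thresholded nutrient is lognormal. Both parameters are
  solved in closed form from two quantile constraints — the per-meal and
  the daily exceedance targets (`P(X > t) = p_meal`, `P(X > d) = p_daily`)
  — whose defaults are the proportions observed in the population this
  emulates (e.g. saturated fat 46.4% / 7.1%). A single free parameter
  (the original design) could match only the per-meal target; using both
  printed targets pins the tail shape too. Degenerate targets (0 or 1)
  fall back to a fixed spread with clipping. Protein, fiber and serving
  weight are lognormal with fixed, realistic parameters (medians 18 g,
  3 g, 300 g; weights clipped to 80–1000 g). Nutrients are drawn
  independently: the generator makes no attempt at energy–macronutrient
  coherence (Atwater consistency), correlated missingness, menu-section
  structure, or item persistence across waves, so passing tests say
  nothing about those aspects of real data.
* **Printing and the guard band.** Ground truth is what a menu would
  print: integer kcal, one-decimal grams (per-100g panels: one decimal for
  energy, two for grams; weights one decimal). Printed values landing
  within ±2 kcal / ±0.3 g of a threshold are nudged to just outside the
  band on the side of the *unrounded* value, so target probabilities are
  preserved exactly while the worst-case harmonization error on any
  emission path (kJ conversion ≤ 0.12 kcal; density reconstruction
  ≤ ~1.8 kcal / ~0.2 g at the clipped weight range) stays strictly inside
  the band — pipeline exceedance flags therefore provably equal
  ground-truth flags, and summaries are exactly recountable from truth.
* **Dialects.** Four built-ins — `classic` (long headers, per-serving,
  kcal, dash missing, thousands separators), `terse` (synonym headers,
  blank missing), `dual` (per-serving + per-100g panels, kcal and kJ),
  `density` (per-100g only with stated weight) — mixed
  0.45/0.35/0.12/0.08 per chain, constant across waves (chains publish in
  one format). Chains on the per-serving dialects report kJ-only with
  probability 0.10. Missingness is per field (13% energy; 3.5–4.5%
  macronutrients; 49% fiber; 75% stated weight) and conditional on energy:
  an item without calorie information reports nothing else, which
  reproduces the real pattern that nutrient denominators sit slightly
  below the energy denominator. Operator wrapping (`<x`, rate 0.02 on
  values ≤ 1 g) wraps the printed value itself, so the conservative
  substitution is lossless.
* **Pizza.** ~4% of chains are pizza chains (fixed to `classic`); 60% of
  their items are pizzas in three sizes. Medium/large emit per-slice
  values and truth is defined as exactly `3 × printed slice value`;
  individual sizes emit the whole pizza. Portion normalization is
  therefore exact, not merely within tolerance.
* **Declared tolerances.** From the rounding rules: energy within 2 kcal,
  grams within 0.3 g, stated weight within 0.5 g, derived weight within
  6% relative. The round-trip requirement (≥ 99.9% of non-missing fields
  recovered within tolerance) holds with margin; observed recovery is
  100%.
* **Determinism.** One seed drives everything through spawned
  `SeedSequence` children per chain-wave; identical (config, seed) gives
  byte-identical output files, and the same seed also fixes non-London
  location selection in the filters.

## Problem sizes used in tests

The suite generates its own data: a 12-chain, two-wave mixed-dialect run
(~4,000 records, with pizza chains and a stale chain) for oracle
equivalence, round-trip and orchestration checks, and a 10-chain
single-wave run of ~5,000 fully-reported items at a uniform 25% per-meal
target for parameter recovery, judged against a 99% binomial interval
computed independently with scipy. The acceptance script runs the
full-scale default conditions. These sizes are the package's reference
configurations; all scale linearly.

## Known limitations

* The synonym map ships with the inventory needed for the built-in
  dialects; real deployments will extend it (unmapped headers are
  surfaced, so gaps are visible, not silent).
* Cross-wave record linkage, menu-item categorization, scraping and PDF
  table extraction are out of scope: the dialect abstraction starts where
  a scraper's raw tables end.
* Exceedance comparisons treat `<x` bounds as the value `x`; with coarse
  bounds this is conservative in the direction of over-counting
  exceedance, matching the substitution rule.
* No statistical comparison between waves or chains is provided — the
  outputs are descriptive counts and proportions.
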