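# oohmenu

A tested, reusable pipeline for **out-of-home (OOH) menu nutrition
surveillance**: it harmonizes the heterogeneous nutrition tables that large
restaurant/café/takeaway chains publish online into canonical per-wave
master tables, applies the survey's inclusion criteria, and computes how
many menu items exceed UK per-meal and daily reference intakes.

It is aimed at public-health nutrition researchers and policy analysts who
monitor the OOH food environment (for example around calorie menu-labelling
regulation) and need the data-cleaning and classification machinery to be
reproducible and auditable, independent of any particular scrape.

## What it computes

For each menu item with a non-missing value of nutrient $j$, the item
*exceeds the per-meal recommendation* when $x_{ij} > t_j$ and *exceeds the
daily reference intake* when $x_{ij} > d_j$, with strict inequalities
(recommendations are phrased "no more than"/"less than"). The daily
reference intakes $d_j$ are the UK adult values — 2000 kcal energy, 70 g
fat, 20 g saturated fat, 260 g carbohydrate, 90 g total sugars, 6 g salt —
and the per-meal thresholds are $t_\text{energy} = 600$ kcal and
$t_j = 0.30\,d_j$ for the other nutrients. Reported proportions are

$$p_j = 100 \cdot \frac{\#\{i : x_{ij} > t_j\}}{\#\{i : x_{ij}\ \text{non-missing}\}}$$

rounded half-away-from-zero to one decimal; pooled analyses count each
wave-item record once per wave. Alongside exceedance, the pipeline reports
item-level *availability*: per wave, how many items give energy, and what
share of those also give each nutrient and a serving weight (stated, or
derived as $100 \times$ per-serving value / per-100g value).

Because real scraped data is not distributable, the package ships a
first-class synthetic generator that emulates source heterogeneity —
synonym headers ("sugar"/"sugars"/"sugar content"), `<0.05` operator
values, dash/blank missing markers, kcal vs kJ energy, per-serving vs
per-100g panels, and per-slice pizza publishing — with exact ground truth,
so every stage is testable end to end.

## Worked example

```python
from oohmenu import GeneratorConfig, generate_dataset, write_dataset
from oohmenu.pipeline import run_all

config = GeneratorConfig.small(n_chains=8, items_per_chain=(80, 120), seed=42)
dataset = generate_dataset(config, seed=42)
write_dataset(dataset, "demo/data")

result = run_all("demo/data", "demo/out", seed=42)
pooled = result.exceedance[result.exceedance.stratum.str.startswith("pooled")]
print(pooled.to_string(index=False))
```

prints

```
    stratum      nutrient  denominator  n_exceed_meal  pct_meal  n_exceed_daily  pct_daily
pooled-2021        energy         1393            362      26.0              10        0.7
pooled-2021           fat         1355            459      33.9              42        3.1
pooled-2021 saturated_fat         1343            612      45.6             107        8.0
pooled-2021  carbohydrate         1342            246      18.3               1        0.1
pooled-2021         sugar         1326            227      17.1               4        0.3
pooled-2021          salt         1340            456      34.0              59        4.4
```

Reading: of the 1393 wave-item records reporting energy across the two
waves of this small run, 362 (26.0%) are above the 600 kcal per-meal
recommendation and 10 (0.7%) above the 2000 kcal daily reference intake;
saturated fat is the worst offender (45.6% above its 6 g per-meal
threshold), exactly the pattern the generator's default calibration
encodes. `demo/out/` also contains one `master_<wave>.csv` per wave (the
compiled, harmonized item table with verbatim source text preserved),
`availability.csv`, `exclusion_audit.csv` (one machine-readable reason per
excluded business/chain/document) and `run_manifest.json` with conserved
per-stage record counts.

The same workflow is available from a shell:

```bash
oohmenu generate --out demo/data --seed 42
oohmenu run-all --in demo/data --out demo/out --seed 42
```

## Layout

- `src/oohmenu/synthetic.py` — generator (dialects, ground truth, frame)
- `src/oohmenu/standardize.py` — header/value harmonization, serving-weight
  derivation, pizza portion normalization, wave master compilation
- `src/oohmenu/filters.py` — business/chain/menu/document inclusion rules
- `src/oohmenu/analysis.py` — thresholds, exceedance flags, summaries
- `src/oohmenu/pipeline.py`, `src/oohmenu/cli.py` — orchestration and CLI
- `docs/methods.md` — model, parameter and design documentation
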