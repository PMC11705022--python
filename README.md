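# reformulate

Monitor packaged-food **reformulation** and its association with **price
change** across two label-database snapshots.

Given two CSV databases of branded food products — one per time point,
each row a product with identity (UPC / retailer ID), TRA food category,
brand type, container and serving sizes, shelf price and per-serving
nutrients — the pipeline:

1. **matches** products one-to-one on (product code, retailer, container
   size), so shrinkflation and relaunches break the match by design;
2. applies the **exclusion cascade** (categories W/X, invalid price,
   incomplete nutrition, profiling-ineligible), logging every step;
3. normalizes prices **per 100 g (or ml)** by container size and
   nutrients by serving size, and computes between-year deltas;
4. classifies each nutrient delta into **five reformulation groups**
   using Daily-Value labelling thresholds (±5 % DV "a little", ±15 % DV
   "a lot"), or relative-to-baseline percentages by configuration;
5. scores products with the **FSANZ Nutrient Profiling Scoring
   Criterion** (table-driven: energy/satfat/sugars/sodium baseline
   points minus fruit-veg-nut-legume, protein and fibre points; category
   pass bounds <1 / <4 / <28) and tracks score changes;
6. runs the **statistical battery**: paired Wilcoxon price comparisons,
   retailer-random-intercept mixed-effects models of price change on
   reformulation group (little-change reference, groups with n < 5
   dropped) and on profiling-score change, chi-square brand-type
   association, and Benjamini–Hochberg adjustment per analysis family;
7. writes a **study report**: exclusion flow, price tables, group
   proportions, contingency tables, score distributions, model
   coefficient tables, and a provenance block — all CSV/JSON,
   byte-reproducible under a fixed seed.

A **synthetic supply generator** produces paired year-1/year-2 databases
with known ground truth (reformulation events drawn as % of DV, injected
price effects, multiplicative inflation, shrinkflation, missingness), so
every stage is testable without proprietary data.

## CLI

```bash
reformulate simulate --seed 42 --n 1000 --out sim/       # synthetic supply + truth
reformulate match    --y1 sim/supply_y1.csv --y2 sim/supply_y2.csv --out m/
reformulate classify --y1 a.csv --y2 b.csv --out c/      # five-group tabulations
reformulate fsanz    --db a.csv --out scores.csv         # NPSC scores per product
reformulate analyze  --y1 a.csv --y2 b.csv --out report/ # full statistics
reformulate run      --config study.yml --seed 1 --out report/
reformulate fixtures --out fx/                           # hand-verified example dbs
```

`study.yml` may either name `y1_path`/`y2_path` or contain a `simulate:`
block with generator settings (see `reformulate.synth.SupplyConfig`).

## Data files

* `src/reformulate/data/column_dictionary.md` — the CSV input format.
* `src/reformulate/data/daily_values.yml` — versioned Daily-Value table
  used by the classifier (editable input, not code).
* `src/reformulate/data/npsc_tables.yml` — versioned FSANZ NPSC point
  schedule (thresholds, caps, protein gate, pass bounds). The scorer is
  entirely table-driven.

Both file versions are recorded in every report's provenance block.

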