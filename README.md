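# cpcf-npm

Nutrient and promotion profiling of ready-to-eat commercially produced
complementary foods (CPCF) — the purées and meals marketed for infants and
young children aged 6–36 months.

Public-health agencies benchmark these products against a nutrient and
promotion profile model (NPM) adapted from the WHO Regional Office for
Europe's model: a product is suitable for promotion only if it meets every
applicable **nutrient-composition requirement** and every applicable
**labelling requirement** for its subcategory, and it must additionally carry
a front-of-pack **high-sugar warning** when too much of its energy comes from
total sugar. This package implements that model end to end as a tested,
reusable pipeline for researchers running market surveys from label data:

* **Categorization** — each product is assigned to exactly one of nine
  purée/meal subcategories (dairy-based desserts, fruit purées,
  vegetable-only purées, vegetable purées with cereals, puréed meals
  with cheese / with meat-fish / without meat-fish, chunky meals with
  meat-fish-cheese / with vegetables) from its ingredient composition,
  product name and texture.
* **Six nutrient requirements** with per-subcategory thresholds:
  no added sugars/sweeteners (mono- and disaccharides, syrups/nectars/honey,
  fruit juices and concentrates excluding lemon/lime, nonsugar sweeteners);
  fruit content (≤5 % by weight, or none at all for vegetable purées);
  energy density ≥60 kcal/100 g; total fat ≤4.5 or ≤6 g/100 kcal;
  protein ≥3 or ≥4 g/100 kcal with the named protein source carrying
  ≥8 % or ≥10 % of product weight; sodium <50 mg/100 kcal *and*
  <50 mg/100 g (<100/<100 where cheese is named). A missing declaration
  for an applicable requirement **fails** that requirement. Salt declared
  instead of sodium is converted as sodium (mg) = salt (g) × 1000 / 2.5.
* **High-sugar warning** — % energy from total sugar (Atwater factor
  4 kcal/g) at or above the subcategory threshold (40 % dairy desserts,
  30 % fruit and vegetable-only purées, 20 % vegetable purées with
  cereals, 15 % all meals) requires the warning; reported separately,
  never part of pass/fail.
* **Seventeen labelling requirements** in five groups — protection of
  breastfeeding (5), claims (5), name/ingredient-list clarity (4),
  spout messages (2), a 12-month maximum-age statement on purées (1) —
  with per-category applicability rules.
* **Market aggregation** — per-subcategory and overall pass proportions
  (% (n) with explicit denominators, half-up rounding to one decimal),
  high-sugar proportions among sugar-declaring products, and
  median [IQR] nutrient summary tables.
* **Synthetic market generator** — seeded product labels with known
  ground truth, emulating a published 459-product Southeast-Asian market
  survey's category mix, nutrient distributions and failure prevalences,
  so the whole pipeline is testable without any proprietary data.

Ingredient, sweetener and claim lexicons and the threshold profile are
editable YAML files shipped with the package and swappable per run.

## Worked example

```python
from cpcf_npm import (ProductLabel, IngredientEntry, NutrientPanel,
                      categorize, assess_nutrients)

p = ProductLabel(
    product_id="EX-001",
    name="Chicken and potato pie",
    ingredients=[IngredientEntry(name="potato", pct_by_weight=40),
                 IngredientEntry(name="chicken", pct_by_weight=9),
                 IngredientEntry(name="water", pct_by_weight=49),
                 IngredientEntry(name="concentrated apple juice", pct_by_weight=2)],
    panel=NutrientPanel(energy_value=70, energy_unit="kcal",
                        total_sugar_g=3.0, salt_g=0.15, total_fat_g=2.0,
                        protein_g=3.2),
)
assignment = categorize(p)
print("subcategory:", assignment.code.value, " (rule:", assignment.rule + ")")
a = assess_nutrients(p, assignment.code)
for req, res in a.results.items():
    print(f"{req.value:15s} {res.status.value:15s} {res.reason or ''}")
print("overall_pass:", a.overall_pass, "| high_sugar:", a.high_sugar.value)
```

prints

```
subcategory: pureed_meal_meat_fish  (rule: meat_fish_first_named)
added_sugar     fail            lexicon_hit
fruit_content   pass
energy_density  pass
fat             pass
protein         fail            named_source_below_weight
sodium          fail            threshold_exceeded
overall_pass: False | high_sugar: warning_required
```

Chicken is the first food in the name, so the product is a puréed meal
with meat/fish. It fails three requirements: the juice concentrate is an
added sugar; chicken, the named protein, is only 9 % of the product by
weight (<10 %); and the salt declaration converts to 60 mg sodium/100 g,
over the <50 limit. With 3 g sugar at 70 kcal/100 g, 17 % of energy comes
from sugar (≥15 % for meals), so a front-of-pack high-sugar warning is
required — reported separately from the pass/fail verdict.

## Command line

```sh
cpcf-npm simulate --n 459 --seed 7 --out sim/        # synthetic market + ground truth
cpcf-npm assess --input sim/products.json --out out/ # per-product records + report tables
cpcf-npm report --input out/assessments.json --out rep/  # re-aggregate saved records
cpcf-npm verify-benchmark                            # benchmark arithmetic self-check
```

`assess` accepts `--profile`, `--lexicon`, `--sweetener-lexicon` and
`--claim-lexicon` to swap the threshold profile or any lexicon; every run
writes a `run_manifest.json`.

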