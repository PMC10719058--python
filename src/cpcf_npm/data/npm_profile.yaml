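# Adapted nutrient profile for commercial complementary-food purées/meals.
# Per-subcategory thresholds for the six nutrient-composition requirements
# and the high-sugar front-of-pack warning.
#
# Units: energy_density_min kcal/100 g; sodium_max [mg/100 kcal, mg/100 g]
# (strict '<' comparisons); fat_max g/100 kcal (inclusive '<='); protein_min
# g/100 kcal (inclusive '>='); named_protein_min_pct % by weight of the
# total product (inclusive '>='); high_sugar_pct_energy % of energy from
# total sugar ('>=' triggers the warning).  'null' marks a requirement not
# applicable to the subcategory.
# fruit_rule: max_5pct_weight = <=5 % by weight fruit/fruit purée (inclusive);
#             no_added_fruit  = no fruit ingredient at all.
# sodium_max_if_cheese_named relaxes the sodium pair when a cheese term
# appears in the front-of-pack product name.
profile: adapted-npm-cpcf-purees-meals
version: 1
thresholds:
  dairy_dessert:
    energy_density_min: 60
    sodium_max: [50, 50]
    sodium_max_if_cheese_named: null
    fat_max: 4.5
    protein_min: null
    named_protein_min_pct: null
    fruit_rule: max_5pct_weight
    high_sugar_pct_energy: 40
  fruit_puree:
    energy_density_min: 60
    sodium_max: [50, 50]
    sodium_max_if_cheese_named: null
    fat_max: 4.5
    protein_min: null
    named_protein_min_pct: null
    fruit_rule: null
    high_sugar_pct_energy: 30
  vegetable_only_puree:
    energy_density_min: 60
    sodium_max: [50, 50]
    sodium_max_if_cheese_named: null
    fat_max: 4.5
    protein_min: null
    named_protein_min_pct: null
    fruit_rule: no_added_fruit
    high_sugar_pct_energy: 30
  vegetable_puree_with_cereal:
    energy_density_min: 60
    sodium_max: [50, 50]
    sodium_max_if_cheese_named: null
    fat_max: 4.5
    protein_min: null
    named_protein_min_pct: null
    fruit_rule: no_added_fruit
    high_sugar_pct_energy: 20
  pureed_meal_cheese:
    energy_density_min: 60
    sodium_max: [100, 100]
    sodium_max_if_cheese_named: null
    fat_max: 6
    protein_min: 3
    named_protein_min_pct: null
    fruit_rule: max_5pct_weight
    high_sugar_pct_energy: 15
  pureed_meal_meat_fish:
    energy_density_min: 60
    sodium_max: [50, 50]
    sodium_max_if_cheese_named: [100, 100]
    fat_max: 6
    protein_min: 4
    named_protein_min_pct: 10
    fruit_rule: max_5pct_weight
    high_sugar_pct_energy: 15
  pureed_meal_no_meat_fish:
    energy_density_min: 60
    sodium_max: [50, 50]
    sodium_max_if_cheese_named: [100, 100]
    fat_max: 4.5
    protein_min: 3
    named_protein_min_pct: 8
    fruit_rule: max_5pct_weight
    high_sugar_pct_energy: 15
  chunky_meal_meat_fish_cheese:
    energy_density_min: null
    sodium_max: [50, 50]
    sodium_max_if_cheese_named: [100, 100]
    fat_max: 6
    protein_min: 4
    named_protein_min_pct: 10
    fruit_rule: max_5pct_weight
    high_sugar_pct_energy: 15
  chunky_meal_vegetable:
    energy_density_min: null
    sodium_max: [50, 50]
    sodium_max_if_cheese_named: [100, 100]
    fat_max: 4.5
    protein_min: 3
    named_protein_min_pct: null
    fruit_rule: max_5pct_weight
    high_sugar_pct_energy: 15
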