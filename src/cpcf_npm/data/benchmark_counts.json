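{
  "description": "Per-subcategory benchmark counts from a 459-product market survey of commercial complementary-food purees/meals across seven Southeast Asian capital cities (2021), used to verify the aggregator's proportion arithmetic against the published percentages.",
  "categories": [
    "dairy_dessert", "fruit_puree", "vegetable_only_puree",
    "vegetable_puree_with_cereal", "pureed_meal_cheese",
    "pureed_meal_meat_fish", "pureed_meal_no_meat_fish",
    "chunky_meal_meat_fish_cheese", "chunky_meal_vegetable"
  ],
  "category_n": [42, 245, 25, 22, 9, 51, 30, 34, 1],
  "nutrient_pass_counts": {
    "added_sugar": [2, 225, 25, 22, 9, 40, 24, 32, 1],
    "fruit_content": [36, null, 24, 13, 6, 42, 24, 34, 1],
    "energy_density": [41, 166, 6, 11, 8, 26, 14, null, null],
    "sodium": [31, 225, 14, 18, 8, 23, 17, 11, 1],
    "fat": [37, 245, 25, 22, 9, 42, 29, 33, 1],
    "protein": [null, null, null, null, 9, 23, 13, 15, 1],
    "all": [0, 144, 3, 6, 4, 6, 3, 6, 1]
  },
  "published_nutrient_pct": {
    "added_sugar": 82.8, "fruit_content": 84.1, "energy_density": 64.2,
    "sodium": 75.8, "fat": 96.5, "protein": 48.8, "all": 37.7
  },
  "sugar_declaring_n": [32, 227, 23, 19, 9, 38, 23, 26, 1],
  "high_sugar_warning_total": 313,
  "published_high_sugar_pct": 78.6,
  "published_sugar_declared_pct": 86.7,
  "labelling": {
    "breastfeeding_subtotal_counts": [3, 28, 0, 0, 1, 5, 1, 1, 0],
    "claims_subtotal_counts": [2, 4, 1, 0, 0, 0, 0, 0, 0],
    "clarity_subtotal_total": 112,
    "spout_subtotal_total": 18,
    "spout_denominator": 250,
    "breastfeeding_message_pass_counts": [6, 49, 2, 1, 4, 10, 4, 2, 0],
    "not_marketed_under_6mo_pass_counts": [34, 154, 13, 17, 6, 50, 21, 31, 1],
    "published": {
      "breastfeeding_subtotal_pct": 8.5,
      "claims_subtotal_pct": 1.5,
      "clarity_subtotal_pct": 24.4,
      "spout_subtotal_pct": 7.2,
      "missing_breastfeeding_message_pct": 83.0,
      "marketed_under_6mo_pct": 28.8
    }
  }
}
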