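# Methods

## The model

The package implements a rule-based nutrient and promotion profile for
ready-to-eat commercial complementary-food purées and meals (children
6–36 months). The unit of analysis is one unique product label; all
evidence comes from the label itself — the ordered ingredient list with
optional percentages by weight, the per-100 g nutrient declaration
panel, the product name, texture, and a set of human-coded label
features. The assessment is purely descriptive: no statistical
inference, only deterministic rules and proportions.

A product is profiled in four stages: subcategory assignment, the six
nutrient-composition requirements, the separately-reported high-sugar
warning, and the seventeen labelling requirements. Aggregation then
produces per-subcategory and overall `% (n)` tables.

## Categorization

The nine subcategory definitions are not mutually exclusive without an
evaluation order, so the categorizer fixes one, from most specific to
most general: texture first (chunky vs puréed); then presence of
meat/fish and whether a meat/fish food is the *first* food named in the
product name; then cheese in the name; then dairy as the largest
ingredient class; then the vegetable-only test (≥95 % vegetables/
legumes + water, no fruit at all, ≤5 % everything else); then
vegetable/cereal-largest with >5 % cereal or pseudocereal; then fruit
largest. A chunky product that matches nothing else is a chunky
vegetable meal (the residual class); a puréed product matching no rule
is an error listing the failed predicates rather than a silent guess.

Two conventions where the definitions are silent:

* "largest ingredient" compares **per-class sums** of stated
  percentages (so yogurt 40 % beats apple 35 % + nothing, but apple
  35 % + pear 10 % would beat yogurt 40 %). Whether the source survey
  summed or took single largest is not recoverable; summing is applied
  uniformly.
* When any percentage is missing, "largest" falls back to the class of
  the first-listed ingredient (ingredient-labelling convention:
  descending weight), and the ≥95 %/>5 % tests evaluate false — the
  conservative reading of label-only information.

Ingredient and name matching run against an editable YAML lexicon
(one synonym list per class); matching is case-insensitive on
normalised word sequences and the longest term wins, so "vegetable oil"
is a fat, not a vegetable.

## Nutrient requirements

Thresholds ship as a versioned YAML profile keyed by subcategory
(`data/npm_profile.yaml`); alternative profiles can be loaded per run
for sensitivity analyses. Comparisons follow the printed operators
verbatim: energy density ≥60 kcal/100 g and fat/protein limits are
inclusive (a tie passes); the sodium limits are strict `<` (a tie
fails). Added sugars are presence/absence against a sweetener lexicon
whose juice class is pattern-based (any ingredient naming a juice)
with a hard lemon/lime exclusion that overrides any match. Fruit purée
as an ingredient is deliberately *not* an added sugar — it is governed
by the separate fruit-content rule.

Missing information fails: any applicable requirement whose inputs are
undeclared is a `fail` with reason `undeclared`. This includes the
derived quantities — fat, protein and sodium per 100 kcal need a
usable energy declaration, so a product without energy fails those
three plus energy density. The ingredient list is mandatory, so the
added-sugar requirement has no undeclared state; fruit content is
undeclared when fruit is present without a stated percentage.

Numeric conventions: salt→sodium divides by 2.5 (mg = g × 1000 / 2.5);
kJ→kcal divides by 4.184; Atwater general factors 4/4/9 kcal per g of
protein/carbohydrate/fat. The % energy from sugar uses the declared
energy by default; a config switch (`sugar_energy_basis="atwater"`)
recomputes the denominator from declared macronutrients instead, which
is only a lower bound on true energy because non-sugar carbohydrate is
not declared on these panels — hence "declared" is the default.

The named-protein weight clause (≥10 % or ≥8 % by weight) reads the
named protein class off the product name and sums the matching
ingredient entries; for meals whose protein source is not first-named,
the clause applies only when a meat/fish term appears in the name at
all, otherwise only the g/100 kcal floor applies. The cheese-named
sodium relaxation (<100 instead of <50) applies to the four classes
that carry it; puréed meals with cheese get the 100-limit outright
since cheese in the name is definitional there.

## Labelling requirements

17 requirements = breastfeeding 5 + claims 5 + clarity 4 + spout 2 +
age restriction 1. Applicability: % fruit stated only for
fruit-containing products; % water only when water is an ingredient;
% protein only for the four meal classes with a named protein focus;
spout messages only when the product has a spout; the 12-month
maximum-age statement only for puréed classes. Not-applicable results
are excluded from all conjunctions, so a group with nothing applicable
passes vacuously. As in the nutrient assessment, a missing coded
feature fails its requirement.

Claims are classified by ordered pattern lists (disease-risk-reduction
first, then nonpermitted compositional, nutrient function, nutrient
content; anything unmatched is "other"). "Marketed as suitable under
6 months" and "recommends bottle feeding" are human-coded booleans, not
inferred — the source information is imagery, outside a text pipeline.

## Aggregation

Every cell is `% (n)` with the denominator stored explicitly;
proportions are `round_half_up(100·n/d, 1)` for display with the raw
fraction retained in JSON. High-sugar proportions are computed among
sugar-declaring products only; median [IQR] nutrient summaries cover
declaring products only, with quartiles by linear interpolation
between order statistics (the convention is not stated by the source
tables; it is fixed and documented here, and no test depends on
real-data quartiles).

## Synthetic data

The generator emulates the structure of a 459-product market survey:
the nine-way category mix (42/245/25/22/9/51/30/34/1), per-subcategory
lognormal nutrient levels with median equal to the published per-100 g
median and σ = ln(q3/q1)/(2·Φ⁻¹(0.75)) fitted to the printed IQR, and
per-requirement violation prevalences defaulting to the published
overall failure rates. Energy density per subcategory is not published
anywhere, so plausible ready-to-eat medians were fixed once (45–85
kcal/100 g, vegetable-only purées lowest, dairy desserts and chunky
meals highest — consistent with the published energy-density pass
rates). The chunky-vegetable class has a single published product, so
its spreads are mild defaults around that product's values.

Violations are injected as certainties, not samples: an intent to fail
a threshold requirement conditions the drawn value onto the failing
side (with a margin so that display rounding cannot flip it), an
added-sugar intent appends a sugar ingredient, a fruit intent swaps in
a template variant containing fruit. Ground truth records the intended
subcategory and per-requirement statuses, and the pipeline must
recover them exactly — this is a structural guarantee of generator/
assessor consistency, not a statistical one. One combination is
categorically infeasible and skipped: a vegetable-only purée cannot
contain fruit (the class definition excludes it), so its fruit intent
is always pass.

What passing on synthetic data does **not** show: real labels carry
free-text ingredients in many languages, partial percentage
declarations, and claim phrasings far beyond the seeded lexicons;
lexicon recall on real markets must be validated separately. The
generator's names come from fixed templates (one per subcategory) that
deliberately exercise the first-named-food logic, not the diversity of
real product naming.

## Problem sizes and determinism

The test suite uses 300–5,000-product synthetic markets; the
acceptance script uses 2,000 products — sizes at which binomial
sampling error on prevalences is well inside the 3-standard-error
bands the tests assert. All randomness flows from one seeded
generator; identical seed and configuration reproduce products and
ground truth byte-for-byte.

## Known limitations

* Category assignment for products whose labels state no percentages
  relies on list order alone; the ≥95 % vegetable-only test can then
  never pass, which under-assigns that class relative to a survey with
  richer information.
* The added-sugar lexicon counts juice concentrates but not non-juice
  "fruit concentrate"; whether surveys count the latter varies.
* The benchmark per-category counts carry the source tables' own
  internal inconsistencies (a clarity subtotal printed two ways, one
  spout cell with % and n disagreeing); the packaged counts follow the
  overall figures as printed and the arithmetic self-check
  (`cpcf-npm verify-benchmark`) documents exactly what is being
  reproduced.
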