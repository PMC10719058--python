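"""Synthetic product-label generator with known ground truth.

No per-product dataset for this market was ever deposited, so every
pipeline stage is exercised against generated labels that emulate the
published market structure: the nine-subcategory mix (42/245/25/22/9/
51/30/34/1 of 459), per-subcategory nutrient levels drawn lognormal
with the median anchored to the published per-100 g medians and the
spread fitted to the printed interquartile ranges, and per-requirement
violation prevalences defaulting to the published overall failure
rates.

Generation constructs each label to *realize* a sampled intent:
violations are injected as certainties (an added-sugar intent appends a
sugar ingredient; an energy-density intent places energy on the chosen
side of 60 kcal/100 g; sodium/fat/protein values are conditioned onto
the intended side of their thresholds), so the categorizer and
assessors must recover the recorded ground truth exactly.  Product
names and ingredient lists come from per-subcategory templates built so
the category rules fire deterministically (first-named-food logic
included).  One fruit-content caveat: a vegetable-only purée cannot
carry a fruit violation — the class definition excludes any fruit — so
that intent is forced to pass there.

All randomness flows from a single seeded generator stream; a fixed
seed reproduces the market byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .categorizer import (CHUNKY_SUBCATEGORIES, PUREED_SUBCATEGORIES,
                          Subcategory)
from .label_model import (Claim, EnergyUnit, IngredientEntry, LabelFeatures,
                          NutrientPanel, ProductLabel, Texture)
from .labelling_assessor import GROUPS, LabellingRequirement
from .nutrient_assessor import (HighSugar, Requirement, Status, ThresholdSet,
                                default_thresholds, pct_energy_from_sugar)

_Z_QUARTILE = 0.6744897501960817  # Φ⁻¹(0.75)

# subcategory order used by the probability vector
CATEGORY_ORDER: tuple[Subcategory, ...] = tuple(Subcategory)

# published market mix: counts per subcategory out of 459
DEFAULT_CATEGORY_COUNTS = (42, 245, 25, 22, 9, 51, 30, 34, 1)

# per-subcategory (median, q1, q3) anchors per 100 g for the declared panel
NUTRIENT_ANCHORS: dict[Subcategory, dict[str, tuple[float, float, float]]] = {
    Subcategory.dairy_dessert: {
        "total_sugar_g": (8.0, 6.4, 10.0), "sodium_mg": (23, 22, 40),
        "protein_g": (2.1, 1.7, 3.3), "total_fat_g": (3.1, 2.8, 3.9)},
    Subcategory.fruit_puree: {
        "total_sugar_g": (10.6, 8.8, 12.1), "sodium_mg": (6, 2, 17),
        "protein_g": (0.9, 0.4, 1.0), "total_fat_g": (0.2, 0.1, 0.4)},
    Subcategory.vegetable_only_puree: {
        "total_sugar_g": (3.3, 2.8, 4.9), "sodium_mg": (18, 7, 27),
        "protein_g": (0.9, 0.9, 1.1), "total_fat_g": (0.1, 0.05, 0.6)},
    Subcategory.vegetable_puree_with_cereal: {
        "total_sugar_g": (2.8, 2.1, 4.6), "sodium_mg": (14, 8, 22),
        "protein_g": (1.7, 1.1, 1.8), "total_fat_g": (0.4, 0.3, 1.0)},
    Subcategory.pureed_meal_cheese: {
        "total_sugar_g": (2.8, 1.6, 2.8), "sodium_mg": (36, 32, 58),
        "protein_g": (2.5, 2.5, 2.9), "total_fat_g": (2.4, 2.4, 2.6)},
    Subcategory.pureed_meal_meat_fish: {
        "total_sugar_g": (1.6, 0.8, 3.2), "sodium_mg": (23, 15, 52),
        "protein_g": (2.9, 2.2, 3.7), "total_fat_g": (1.2, 0.6, 1.6)},
    Subcategory.pureed_meal_no_meat_fish: {
        "total_sugar_g": (2.4, 0.8, 3.5), "sodium_mg": (28, 20, 60),
        "protein_g": (2.7, 2.2, 3.2), "total_fat_g": (1.3, 0.8, 2.2)},
    Subcategory.chunky_meal_meat_fish_cheese: {
        "total_sugar_g": (1.1, 0.7, 1.6), "sodium_mg": (46, 23, 66),
        "protein_g": (3.0, 2.3, 3.7), "total_fat_g": (1.6, 1.2, 2.2)},
    Subcategory.chunky_meal_vegetable: {
        "total_sugar_g": (1.4, 1.1, 1.8), "sodium_mg": (22, 18, 28),
        "protein_g": (2.8, 2.4, 3.2), "total_fat_g": (0.9, 0.7, 1.2)},
}

# energy density anchors (kcal/100 g): not published per subcategory;
# plausible ready-to-eat purée/meal levels chosen once (see docs/methods.md)
ENERGY_ANCHORS: dict[Subcategory, tuple[float, float, float]] = {
    Subcategory.dairy_dessert: (85, 75, 100),
    Subcategory.fruit_puree: (65, 55, 75),
    Subcategory.vegetable_only_puree: (45, 38, 55),
    Subcategory.vegetable_puree_with_cereal: (60, 50, 72),
    Subcategory.pureed_meal_cheese: (80, 70, 90),
    Subcategory.pureed_meal_meat_fish: (70, 60, 85),
    Subcategory.pureed_meal_no_meat_fish: (65, 55, 80),
    Subcategory.chunky_meal_meat_fish_cheese: (80, 65, 95),
    Subcategory.chunky_meal_vegetable: (75, 60, 90),
}

# published overall failure rates per nutrient requirement
DEFAULT_FAILURE_PREVALENCES: dict[str, float] = {
    "added_sugar": 0.172, "fruit_content": 0.159, "energy_density": 0.358,
    "sodium": 0.242, "fat": 0.035, "protein": 0.512,
}

# published overall failure / absence rates per labelling requirement
DEFAULT_LABELLING_FAIL_PREVALENCES: dict[str, float] = {
    "min_age_6mo": 0.274,
    "not_marketed_under_6mo": 0.288,
    "breastfeeding_2yr_message": 0.830,
    "no_superiority_to_breastmilk": 0.035,
    "no_bottle_feeding_promotion": 0.0,
    "no_nonpermitted_compositional_claims": 0.950,
    "no_nutrient_content_claims": 0.250,
    "no_nutrient_function_claims": 0.039,
    "no_disease_risk_reduction_claims": 0.0,
    "no_other_claims": 0.808,
    "name_reflects_ingredient_order": 0.407,
    "pct_fruit_stated": 0.342,
    "pct_water_stated": 0.731,
    "pct_protein_stated": 0.172,
    "spout_no_suck_message": 0.824,
    "spout_choke_warning": 0.240,
    "max_age_12mo_stated": 0.995,
}

# published share of products lacking each declaration
DEFAULT_MISSINGNESS: dict[str, float] = {
    "energy": 0.0, "total_sugar_g": 0.133, "sodium_mg": 0.059,
    "total_fat_g": 0.022, "protein_g": 0.0,
}

DEFAULT_SPOUT_RATE = 250 / 424  # spouted share among puréed products

_CLAIM_TEXTS = {
    "no_nonpermitted_compositional_claims": "no added sugar",
    "no_nutrient_content_claims": "high in vitamin C",
    "no_nutrient_function_claims": "supports healthy growth",
    "no_disease_risk_reduction_claims": "helps reduce the risk of infection",
    "no_other_claims": "easy to carry anywhere",
}


@dataclass
class MarketConfig:
    """Study conditions for one synthetic market."""

    n_products: int = 459
    category_mix: tuple[float, ...] = tuple(c / sum(DEFAULT_CATEGORY_COUNTS)
                                            for c in DEFAULT_CATEGORY_COUNTS)
    failure_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAILURE_PREVALENCES))
    labelling_fail_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABELLING_FAIL_PREVALENCES))
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    spout_rate: float = DEFAULT_SPOUT_RATE
    seed: int = 0

    def validate(self) -> None:
        if self.n_products < 0:
            raise ValueError("n_products must be >= 0")
        if len(self.category_mix) != len(CATEGORY_ORDER):
            raise ValueError("category_mix must have 9 entries")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        for name, probs in (("category_mix", self.category_mix),
                            ("failure_prevalences", self.failure_prevalences.values()),
                            ("labelling_fail_prevalences",
                             self.labelling_fail_prevalences.values()),
                            ("missingness_rates", self.missingness_rates.values()),
                            ("spout_rate", [self.spout_rate])):
            for p in probs:
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name}: probability {p} outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Intended outcome for one generated product."""
    product_id: str
    subcategory: Subcategory
    nutrient_status: dict[str, str]      # requirement -> pass/fail/not_applicable
    high_sugar: str
    labelling_status: dict[str, str]
    overall_nutrient_pass: bool

    def to_json_dict(self) -> dict:
        return {"product_id": self.product_id,
                "subcategory": self.subcategory.value,
                "nutrient_status": dict(self.nutrient_status),
                "high_sugar": self.high_sugar,
                "labelling_status": dict(self.labelling_status),
                "overall_nutrient_pass": self.overall_nutrient_pass}


# ---------------------------------------------------------------------------
# label templates: (product name, [(ingredient, pct), ...]) per subcategory;
# the fruit-violation variant swaps in a list containing added fruit
# ---------------------------------------------------------------------------

_TEMPLATES: dict[Subcategory, dict] = {
    Subcategory.dairy_dessert: {
        "name": "Yogurt and apple dessert",
        "base": [("yogurt", 75.0), ("rice flour", 15.0), ("water", 6.0),
                 ("apple", 4.0)],
        "fruit_violation": [("yogurt", 55.0), ("rice flour", 10.0),
                            ("water", 15.0), ("apple", 20.0)],
    },
    Subcategory.fruit_puree: {
        "name": "Apple and banana puree",
        "base": [("apple", 60.0), ("banana", 30.0), ("water", 10.0)],
        "fruit_violation": None,  # fruit rule not applicable
    },
    Subcategory.vegetable_only_puree: {
        "name": "Carrot and pea puree",
        "base": [("carrot", 59.0), ("green peas", 20.0), ("water", 19.0),
                 ("rapeseed oil", 2.0)],
        "fruit_violation": None,  # infeasible: class excludes any fruit
    },
    Subcategory.vegetable_puree_with_cereal: {
        "name": "Carrot and pasta meal",
        "base": [("carrot", 45.0), ("pasta", 30.0), ("water", 21.0),
                 ("rapeseed oil", 4.0)],
        "fruit_violation": [("carrot", 40.0), ("pasta", 30.0), ("apple", 10.0),
                            ("water", 16.0), ("rapeseed oil", 4.0)],
    },
    Subcategory.pureed_meal_cheese: {
        "name": "Cheesy cauliflower bake",
        "base": [("cauliflower", 45.0), ("pasta", 25.0), ("water", 18.0),
                 ("cheese", 10.0), ("cream", 2.0)],
        "fruit_violation": [("cauliflower", 35.0), ("pasta", 22.0),
                            ("apple", 15.0), ("water", 16.0), ("cheese", 10.0),
                            ("cream", 2.0)],
    },
    Subcategory.pureed_meal_meat_fish: {
        "name": "Chicken and potato pie",
        "base": [("potato", 35.0), ("chicken", 30.0), ("water", 30.0),
                 ("rapeseed oil", 5.0)],
        "fruit_violation": [("potato", 30.0), ("chicken", 28.0),
                            ("apple", 10.0), ("water", 27.0),
                            ("rapeseed oil", 5.0)],
    },
    Subcategory.pureed_meal_no_meat_fish: {
        "name": "Carrot, potato and lamb hotpot",
        "base": [("carrot", 30.0), ("potato", 28.0), ("water", 27.0),
                 ("lamb", 12.0), ("rapeseed oil", 3.0)],
        "fruit_violation": [("carrot", 26.0), ("potato", 24.0), ("apple", 10.0),
                            ("water", 25.0), ("lamb", 12.0),
                            ("rapeseed oil", 3.0)],
    },
    Subcategory.chunky_meal_meat_fish_cheese: {
        "name": "Salmon and pea risotto",
        "base": [("rice", 35.0), ("salmon", 25.0), ("green peas", 20.0),
                 ("water", 20.0)],
        "fruit_violation": [("rice", 31.0), ("salmon", 25.0),
                            ("green peas", 18.0), ("apple", 10.0),
                            ("water", 16.0)],
    },
    Subcategory.chunky_meal_vegetable: {
        "name": "Garden vegetable stew",
        "base": [("potato", 40.0), ("carrot", 25.0), ("green peas", 15.0),
                 ("water", 20.0)],
        "fruit_violation": [("potato", 36.0), ("carrot", 23.0),
                            ("green peas", 13.0), ("apple", 10.0),
                            ("water", 18.0)],
    },
}


def _fit_lognormal(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given median and quartiles.

    sigma = ln(q3/q1) / (2·Φ⁻¹(0.75)); falls back to a moderate spread
    when the printed quartiles are degenerate or touch zero.
    """
    mu = math.log(max(median, 1e-6))
    if q1 > 0 and q3 > q1:
        sigma = math.log(q3 / q1) / (2 * _Z_QUARTILE)
    else:
        sigma = 0.4
    return mu, sigma


def _draw(rng: np.random.Generator, anchor: tuple[float, float, float]) -> float:
    mu, sigma = _fit_lognormal(*anchor)
    return float(rng.lognormal(mu, sigma))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_market(config: Optional[MarketConfig] = None,
                    ) -> tuple[list[ProductLabel], list[GroundTruth]]:
    """Generate a seeded, reproducible synthetic market with ground truth."""
    cfg = config or MarketConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    thresholds = default_thresholds()
    products: list[ProductLabel] = []
    truths: list[GroundTruth] = []
    cat_indices = rng.choice(len(CATEGORY_ORDER), size=cfg.n_products,
                             p=np.asarray(cfg.category_mix, dtype=float))
    for i in range(cfg.n_products):
        cat = CATEGORY_ORDER[int(cat_indices[i])]
        pid = f"SYN-{i:05d}"
        product, truth = _generate_product(rng, pid, cat, thresholds[cat], cfg)
        products.append(product)
        truths.append(truth)
    return products, truths


def _generate_product(rng: np.random.Generator, pid: str, cat: Subcategory,
                      t: ThresholdSet, cfg: MarketConfig
                      ) -> tuple[ProductLabel, GroundTruth]:
    tpl = _TEMPLATES[cat]
    prev = cfg.failure_prevalences
    miss = cfg.missingness_rates
    nutrient_status: dict[str, str] = {}

    # --- ingredient-driven requirements ---
    add_sugar = rng.random() < prev.get("added_sugar", 0.0)
    nutrient_status["added_sugar"] = "fail" if add_sugar else "pass"

    if t.fruit_rule is None:
        fruit_violation = False
        nutrient_status["fruit_content"] = "not_applicable"
    elif tpl["fruit_violation"] is None:
        fruit_violation = False
        nutrient_status["fruit_content"] = "pass"
    else:
        fruit_violation = rng.random() < prev.get("fruit_content", 0.0)
        nutrient_status["fruit_content"] = "fail" if fruit_violation else "pass"

    base = tpl["fruit_violation"] if fruit_violation else tpl["base"]
    ingredients = [list(pair) for pair in base]
    if add_sugar:
        ingredients[0][1] -= 2.0
        ingredients.append(["sugar", 2.0])

    # --- panel: missingness, then intent-conditioned values ---
    energy_missing = rng.random() < miss.get("energy", 0.0)
    sugar_missing = rng.random() < miss.get("total_sugar_g", 0.0)
    sodium_missing = rng.random() < miss.get("sodium_mg", 0.0)
    fat_missing = rng.random() < miss.get("total_fat_g", 0.0)
    protein_missing = rng.random() < miss.get("protein_g", 0.0)

    energy = None if energy_missing else _draw(rng, ENERGY_ANCHORS[cat])
    if t.energy_density_min is None:
        nutrient_status["energy_density"] = "not_applicable"
    elif energy is None:
        nutrient_status["energy_density"] = "fail"
    else:
        lo = t.energy_density_min
        if rng.random() < prev.get("energy_density", 0.0):
            if energy >= lo:
                energy = float(rng.uniform(0.6 * lo, 0.97 * lo))
            nutrient_status["energy_density"] = "fail"
        else:
            if energy < lo:
                energy = float(rng.uniform(1.02 * lo, 1.5 * lo))
            nutrient_status["energy_density"] = "pass"

    anchors = NUTRIENT_ANCHORS[cat]
    sugar = None if sugar_missing else _draw(rng, anchors["total_sugar_g"])

    sodium = None if sodium_missing else _draw(rng, anchors["sodium_mg"])
    if sodium is None or energy is None:
        nutrient_status["sodium"] = "fail"
    else:
        kcal_cap = t.sodium_max[0] * energy / 100.0
        if rng.random() < prev.get("sodium", 0.0):
            sodium = 1.2 * max(t.sodium_max[1], kcal_cap)
            nutrient_status["sodium"] = "fail"
        else:
            sodium = min(sodium, 0.8 * t.sodium_max[1], 0.8 * kcal_cap)
            nutrient_status["sodium"] = "pass"

    fat = None if fat_missing else _draw(rng, anchors["total_fat_g"])
    if fat is None or energy is None:
        nutrient_status["fat"] = "fail"
    else:
        cap = t.fat_max * energy / 100.0
        if rng.random() < prev.get("fat", 0.0):
            fat = 1.25 * cap
            nutrient_status["fat"] = "fail"
        else:
            fat = min(fat, 0.9 * cap)
            nutrient_status["fat"] = "pass"

    protein = None if protein_missing else _draw(rng, anchors["protein_g"])
    if t.protein_min is None:
        nutrient_status["protein"] = "not_applicable"
    elif protein is None or energy is None:
        nutrient_status["protein"] = "fail"
    else:
        floor = t.protein_min * energy / 100.0
        if rng.random() < prev.get("protein", 0.0):
            protein = 0.7 * floor
            nutrient_status["protein"] = "fail"
        else:
            protein = max(protein, 1.1 * floor)
            nutrient_status["protein"] = "pass"

    pct_sugar = pct_energy_from_sugar(sugar, energy)
    if pct_sugar is None:
        high_sugar = HighSugar.sugar_undeclared
    elif pct_sugar >= t.high_sugar_pct_energy:
        high_sugar = HighSugar.warning_required
    else:
        high_sugar = HighSugar.not_required

    # --- labelling features ---
    lprev = cfg.labelling_fail_prevalences
    labelling_status: dict[str, str] = {}

    def sample_fail(key: str) -> bool:
        failed = rng.random() < lprev.get(key, 0.0)
        labelling_status[key] = "fail" if failed else "pass"
        return failed

    min_age = 4 if sample_fail("min_age_6mo") else 6
    marketed = sample_fail("not_marketed_under_6mo")
    bf_message = not sample_fail("breastfeeding_2yr_message")
    superiority = sample_fail("no_superiority_to_breastmilk")
    bottle = sample_fail("no_bottle_feeding_promotion")

    claims: list[Claim] = []
    for key, text in _CLAIM_TEXTS.items():
        if sample_fail(key):
            claims.append(Claim(text=text))

    name_order = not sample_fail("name_reflects_ingredient_order")

    has_fruit = any(name == "apple" or name == "banana"
                    for name, _ in ingredients)
    if has_fruit:
        pct_fruit: Optional[bool] = not sample_fail("pct_fruit_stated")
    else:
        pct_fruit = None
        labelling_status["pct_fruit_stated"] = "not_applicable"
    pct_water = not sample_fail("pct_water_stated")  # all templates add water
    if cat in (Subcategory.pureed_meal_meat_fish,
               Subcategory.pureed_meal_no_meat_fish,
               Subcategory.chunky_meal_meat_fish_cheese,
               Subcategory.chunky_meal_vegetable):
        pct_protein: Optional[bool] = not sample_fail("pct_protein_stated")
    else:
        pct_protein = None
        labelling_status["pct_protein_stated"] = "not_applicable"

    pureed = cat in PUREED_SUBCATEGORIES
    has_spout = pureed and rng.random() < cfg.spout_rate
    if has_spout:
        no_suck = not sample_fail("spout_no_suck_message")
        choke = not sample_fail("spout_choke_warning")
    else:
        no_suck = choke = None
        labelling_status["spout_no_suck_message"] = "not_applicable"
        labelling_status["spout_choke_warning"] = "not_applicable"
    if pureed:
        max_age = not sample_fail("max_age_12mo_stated")
    else:
        max_age = None
        labelling_status["max_age_12mo_stated"] = "not_applicable"

    product = ProductLabel(
        product_id=pid,
        name=tpl["name"],
        country="SYN",
        ingredients=[IngredientEntry(name=n, pct_by_weight=p)
                     for n, p in ingredients],
        panel=NutrientPanel(
            energy_value=None if energy is None else round(energy, 1),
            energy_unit=None if energy is None else EnergyUnit.kcal,
            total_sugar_g=None if sugar is None else round(sugar, 2),
            sodium_mg=None if sodium is None else round(sodium, 1),
            total_fat_g=None if fat is None else round(fat, 2),
            protein_g=None if protein is None else round(protein, 2),
        ),
        features=LabelFeatures(
            min_age_months_stated=min_age,
            marketed_under_6mo=marketed,
            breastfeeding_2yr_message=bf_message,
            suggests_superiority_to_breastmilk=superiority,
            recommends_bottle_feeding=bottle,
            claims=claims,
            name_reflects_ingredient_order=name_order,
            pct_fruit_stated=pct_fruit,
            pct_water_stated=pct_water,
            pct_protein_stated=pct_protein,
            has_spout=has_spout,
            spout_no_suck_message=no_suck,
            spout_choke_warning=choke,
            max_age_12mo_stated=max_age,
            texture=Texture.chunky if cat in CHUNKY_SUBCATEGORIES
            else Texture.pureed,
        ),
    )
    # rounding of the declared value must not flip an intended outcome
    _reconcile_rounding(product, t, nutrient_status)
    truth = GroundTruth(
        product_id=pid, subcategory=cat,
        nutrient_status=nutrient_status,
        high_sugar=_high_sugar_after_rounding(product, t).value,
        labelling_status=labelling_status,
        overall_nutrient_pass=all(s != "fail" for s in nutrient_status.values()),
    )
    return product, truth


def _high_sugar_after_rounding(p: ProductLabel, t: ThresholdSet) -> HighSugar:
    pct = pct_energy_from_sugar(p.panel.total_sugar_g, p.panel.energy_value)
    if pct is None:
        return HighSugar.sugar_undeclared
    return (HighSugar.warning_required if pct >= t.high_sugar_pct_energy
            else HighSugar.not_required)


def _reconcile_rounding(p: ProductLabel, t: ThresholdSet,
                        status: dict[str, str]) -> None:
    """Nudge declared values whose rounding crossed an intended threshold."""
    panel = p.panel
    e = panel.energy_value
    if e is None:
        return
    if t.energy_density_min is not None:
        if status["energy_density"] == "pass" and e < t.energy_density_min:
            panel.energy_value = t.energy_density_min
        if status["energy_density"] == "fail" and e >= t.energy_density_min:
            panel.energy_value = t.energy_density_min - 1.0
        e = panel.energy_value
    if panel.sodium_mg is not None and status["sodium"] == "pass":
        cap = min(t.sodium_max[1], t.sodium_max[0] * e / 100.0)
        if panel.sodium_mg >= cap:
            panel.sodium_mg = round(0.8 * cap, 1)
    if panel.total_fat_g is not None and status["fat"] == "pass":
        cap = t.fat_max * e / 100.0
        if panel.total_fat_g > cap:
            panel.total_fat_g = round(0.9 * cap, 2)
    if (panel.protein_g is not None and t.protein_min is not None
            and status["protein"] == "pass"):
        floor = t.protein_min * e / 100.0
        if panel.protein_g < floor:
            panel.protein_g = round(1.1 * floor, 2)
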