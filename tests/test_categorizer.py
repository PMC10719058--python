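"""Subcategory assignment: lexicon lookups, first-named food, the nine
category rules and equivalence with a brute-force evaluation of the
category definitions."""

import numpy as np
import pytest

from cpcf_npm import (IngredientClass, Subcategory, UncategorizableError,
                      categorize, classify_ingredient, first_named_food)
from cpcf_npm.categorizer import CHUNKY_SUBCATEGORIES
from cpcf_npm.label_model import Texture
from tests.conftest import make_product


@pytest.mark.parametrize("name,expected", [
    ("whole milk yogurt", IngredientClass.dairy),
    ("quinoa", IngredientClass.pseudocereal),
    ("buckwheat", IngredientClass.pseudocereal),
    ("courgette", IngredientClass.vegetable),
    ("rapeseed oil", IngredientClass.oil_fat),
    ("vegetable oil", IngredientClass.oil_fat),   # longest match beats 'vegetable'
    ("green peas", IngredientClass.legume),
    ("cheddar cheese", IngredientClass.cheese),
    ("mystery ingredient x", IngredientClass.unclassified),
])
def test_classify_ingredient(name, expected):
    assert classify_ingredient(name) == expected


@pytest.mark.parametrize("name,expected", [
    ("Salmon and pea risotto", IngredientClass.fish),
    ("Hearty shepherd's pie", None),
    ("Cheesy pasta with tomato", IngredientClass.cheese),
    ("Carrot, potato and lamb hotpot", IngredientClass.vegetable),
    ("Chicken and potato pie", IngredientClass.meat),
])
def test_first_named_food(name, expected):
    assert first_named_food(name) == expected


@pytest.mark.parametrize("kwargs,expected", [
    # >=95% vegetables/legumes + water, no fruit
    (dict(name="Carrot puree",
          ingredients=(("carrot", 70.0), ("water", 28.0), ("rapeseed oil", 2.0))),
     Subcategory.vegetable_only_puree),
    (dict(name="Apple puree", ingredients=(("apple", 100.0),)),
     Subcategory.fruit_puree),
    (dict(name="Salmon and pea risotto", texture="chunky",
          ingredients=(("rice", 40.0), ("salmon", 25.0), ("green peas", 20.0),
                       ("water", 15.0))),
     Subcategory.chunky_meal_meat_fish_cheese),
    # dairy 40 > fruit 35 and > grain 25
    (dict(name="Yogurt with apple and oats",
          ingredients=(("yogurt", 40.0), ("apple", 35.0), ("oats", 25.0))),
     Subcategory.dairy_dessert),
    # vegetable largest with >5% cereal
    (dict(name="Carrot and pasta meal",
          ingredients=(("carrot", 50.0), ("pasta", 30.0), ("water", 20.0))),
     Subcategory.vegetable_puree_with_cereal),
    # cheese in name, no meat/fish
    (dict(name="Cheesy pasta with tomato",
          ingredients=(("tomato", 40.0), ("pasta", 30.0), ("water", 20.0),
                       ("cheese", 10.0))),
     Subcategory.pureed_meal_cheese),
    # meat present but not first-named
    (dict(name="Carrot, potato and lamb hotpot",
          ingredients=(("carrot", 30.0), ("potato", 28.0), ("water", 30.0),
                       ("lamb", 12.0))),
     Subcategory.pureed_meal_no_meat_fish),
    # meat first-named
    (dict(name="Chicken and potato pie",
          ingredients=(("potato", 35.0), ("chicken", 30.0), ("water", 35.0))),
     Subcategory.pureed_meal_meat_fish),
    # chunky residual
    (dict(name="Garden vegetable stew", texture="chunky",
          ingredients=(("potato", 40.0), ("carrot", 30.0), ("water", 30.0))),
     Subcategory.chunky_meal_vegetable),
])
def test_categorize_rules(kwargs, expected):
    assert categorize(make_product(**kwargs)).code == expected


def test_missing_percentages_fall_back_to_list_order():
    # first-listed ingredient decides 'largest'; the 95% test needs stated pcts
    p = make_product(name="Apple and yogurt pot",
                     ingredients=(("apple", None), ("yogurt", None)))
    assert categorize(p).code == Subcategory.fruit_puree


def test_uncategorizable_pureed_product_raises():
    p = make_product(name="Mystery blend",
                     ingredients=(("rapeseed oil", 60.0), ("water", 40.0)))
    with pytest.raises(UncategorizableError) as exc:
        categorize(p)
    assert exc.value.failed_predicates


def test_determinism_and_texture_invariant():
    from cpcf_npm import MarketConfig, generate_market
    products, _ = generate_market(MarketConfig(n_products=150, seed=11))
    for p in products:
        a, b = categorize(p), categorize(p)
        assert a == b
        assert (a.code in CHUNKY_SUBCATEGORIES) == (p.features.texture == Texture.chunky)


# ---------------------------------------------------------------------------
# brute-force oracle: an independent straight-line evaluation of the
# category definitions on small fully-percentaged ingredient lists
# ---------------------------------------------------------------------------

_POOL = {  # independent name -> class map (not the package lexicon)
    "apple": "fruit", "banana": "fruit", "carrot": "vegetable",
    "potato": "vegetable", "tomato": "vegetable", "green peas": "legume",
    "lentil": "legume", "water": "water", "yogurt": "dairy", "cream": "dairy",
    "pasta": "cereal", "rice": "cereal", "quinoa": "pseudocereal",
    "cheese": "cheese", "chicken": "meat", "salmon": "fish",
    "rapeseed oil": "oil", "sugar": "sugar",
}


def _oracle(names, pcts, meat_fish_first, cheese_in_name, texture):
    """Straight-line re-statement of the category rules."""
    classes = [_POOL[n] for n in names]
    sums = {}
    for c, w in zip(classes, pcts):
        sums[c] = sums.get(c, 0.0) + w
    if texture == "chunky":
        return ("chunky_meal_meat_fish_cheese" if meat_fish_first
                else "chunky_meal_vegetable")
    if "meat" in classes or "fish" in classes:
        return ("pureed_meal_meat_fish" if meat_fish_first
                else "pureed_meal_no_meat_fish")
    if cheese_in_name:
        return "pureed_meal_cheese"
    largest = max(sums, key=sums.get)
    if largest == "dairy":
        return "dairy_dessert"
    vlw = sums.get("vegetable", 0) + sums.get("legume", 0) + sums.get("water", 0)
    rest = sum(sums.values()) - vlw
    if "fruit" not in classes and vlw >= 95.0 and rest <= 5.0:
        return "vegetable_only_puree"
    cereal = sums.get("cereal", 0) + sums.get("pseudocereal", 0)
    if largest in ("vegetable", "legume", "cereal", "pseudocereal") and cereal > 5.0:
        return "vegetable_puree_with_cereal"
    if largest == "fruit":
        return "fruit_puree"
    return None


def test_categorize_agrees_with_brute_force_oracle():
    rng = np.random.default_rng(42)
    pool = list(_POOL)
    checked = 0
    for _ in range(400):
        k = int(rng.integers(2, 6))
        names = list(rng.choice(pool, size=k, replace=False))
        raw = rng.dirichlet(np.ones(k))
        pcts = [round(float(x) * 100, 1) for x in raw]
        pcts[0] = round(100.0 - sum(pcts[1:]), 1)
        texture = "chunky" if rng.random() < 0.2 else "pureed"
        # product name leads with the first ingredient so both sides agree
        # on the first-named food; the name mentions the first two foods
        pname = f"{names[0].title()} and {names[1]} meal"
        meat_fish_first = _POOL[names[0]] in ("meat", "fish")
        cheese_in_name = "cheese" in (_POOL[names[0]], _POOL[names[1]])
        expected = _oracle(names, pcts, meat_fish_first, cheese_in_name, texture)
        p = make_product(name=pname, texture=texture,
                         ingredients=tuple(zip(names, pcts)))
        if expected is None:
            with pytest.raises(UncategorizableError):
                categorize(p)
        else:
            assert categorize(p).code.value == expected, (names, pcts, texture)
        checked += 1
    assert checked == 400
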