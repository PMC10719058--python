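"""Unit conversions, threshold boundary behaviour, the missing-declaration
rule, the overall pass conjunction, and equivalence with an independent
straight-line re-implementation of the requirement formulas."""

import itertools

import pytest

from cpcf_npm import (HighSugar, MarketConfig, NutrientPanel, Requirement,
                      Status, Subcategory, assess_nutrients,
                      energy_kcal_per_100g, generate_market,
                      pct_energy_from_sugar, per_100kcal, salt_to_sodium)
from cpcf_npm.label_model import EnergyUnit
from tests.conftest import make_product


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("salt,expected", [(1.25, 500.0), (0.0, 0.0), (0.10, 40.0)])
def test_salt_to_sodium(salt, expected):
    assert salt_to_sodium(salt) == pytest.approx(expected)


def test_salt_to_sodium_rejects_negative():
    with pytest.raises(ValueError):
        salt_to_sodium(-0.1)


def test_energy_kcal_per_100g():
    assert energy_kcal_per_100g(NutrientPanel(
        energy_value=60, energy_unit=EnergyUnit.kcal)) == 60.0
    assert energy_kcal_per_100g(NutrientPanel(
        energy_value=252, energy_unit=EnergyUnit.kJ)) == pytest.approx(60.23, abs=0.005)
    assert energy_kcal_per_100g(NutrientPanel()) is None


def test_per_100kcal():
    assert per_100kcal(46, 80) == pytest.approx(57.5)
    assert per_100kcal(3.0, 100) == pytest.approx(3.0)
    assert per_100kcal(3.0, None) is None
    assert per_100kcal(None, 80) is None
    assert per_100kcal(3.0, 0.0) is None


def test_pct_energy_from_sugar():
    assert pct_energy_from_sugar(10, 100) == pytest.approx(40.0)
    assert pct_energy_from_sugar(10.6, 60) == pytest.approx(70.67, abs=0.005)
    assert pct_energy_from_sugar(0, 80) == 0.0
    assert pct_energy_from_sugar(None, 80) is None


# ---------------------------------------------------------------------------
# boundary behaviour at every threshold: value = threshold lands on the
# printed side (>=/<= inclusive-pass, < strict-fail)
# ---------------------------------------------------------------------------

def _fruit_puree(**kw):
    return make_product(name="Apple puree", ingredients=(("apple", 100.0),), **kw)


@pytest.mark.parametrize("energy,expected", [
    (60.0, Status.ok), (60.01, Status.ok), (59.99, Status.fail)])
def test_energy_density_boundary_inclusive_at_60(energy, expected):
    a = assess_nutrients(_fruit_puree(energy=energy), Subcategory.fruit_puree)
    assert a[Requirement.energy_density].status == expected


@pytest.mark.parametrize("sodium,energy,expected", [
    (50.0, 100.0, Status.fail),    # tie at '<' threshold fails (per 100 kcal & 100 g)
    (49.99, 100.0, Status.ok),
    (50.0, 200.0, Status.fail),    # per-100 g branch alone trips
    (49.99, 200.0, Status.ok),
    (40.0, 50.0, Status.fail),     # 80 mg/100 kcal at low energy density
])
def test_sodium_boundary_strict_at_50(sodium, energy, expected):
    a = assess_nutrients(_fruit_puree(sodium=sodium, energy=energy),
                         Subcategory.fruit_puree)
    assert a[Requirement.sodium].status == expected


@pytest.mark.parametrize("fat,expected", [
    (4.5, Status.ok), (4.51, Status.fail)])
def test_fat_boundary_inclusive_at_4_5_per_100kcal(fat, expected):
    a = assess_nutrients(_fruit_puree(fat=fat, energy=100.0),
                         Subcategory.fruit_puree)
    assert a[Requirement.fat].status == expected


def _no_mf_meal(lamb_pct=12.0, **kw):
    return make_product(
        name="Carrot, potato and lamb hotpot",
        ingredients=(("carrot", 30.0), ("potato", 30.0 - (lamb_pct - 12.0)),
                     ("water", 28.0), ("lamb", lamb_pct)),
        **kw)


@pytest.mark.parametrize("protein,expected", [
    (3.0, Status.ok), (2.99, Status.fail)])
def test_protein_density_boundary_inclusive_at_3(protein, expected):
    a = assess_nutrients(_no_mf_meal(protein=protein, energy=100.0),
                         Subcategory.pureed_meal_no_meat_fish)
    assert a[Requirement.protein].status == expected


@pytest.mark.parametrize("lamb_pct,expected", [
    (8.0, Status.ok), (7.9, Status.fail)])
def test_named_protein_weight_boundary_inclusive_at_8pct(lamb_pct, expected):
    a = assess_nutrients(_no_mf_meal(lamb_pct=lamb_pct, protein=4.0, energy=100.0),
                         Subcategory.pureed_meal_no_meat_fish)
    assert a[Requirement.protein].status == expected


def test_named_protein_10pct_rule_for_meat_fish_meals():
    # 'Chicken and potato pie' with chicken at 9% by weight fails despite
    # adequate protein density; 10% passes
    def pie(chicken_pct):
        return make_product(
            name="Chicken and potato pie",
            ingredients=(("potato", 40.0), ("chicken", chicken_pct),
                         ("water", 60.0 - chicken_pct)),
            protein=4.2, energy=100.0)
    fail = assess_nutrients(pie(9.0), Subcategory.pureed_meal_meat_fish)
    assert fail[Requirement.protein].status == Status.fail
    assert fail[Requirement.protein].reason == "named_source_below_weight"
    ok = assess_nutrients(pie(10.0), Subcategory.pureed_meal_meat_fish)
    assert ok[Requirement.protein].status == Status.ok


@pytest.mark.parametrize("apple_pct,expected", [
    (5.0, Status.ok), (5.01, Status.fail)])
def test_fruit_weight_boundary_inclusive_at_5pct(apple_pct, expected):
    p = make_product(name="Yogurt dessert",
                     ingredients=(("yogurt", 80.0), ("apple", apple_pct),
                                  ("water", 20.0 - apple_pct)))
    a = assess_nutrients(p, Subcategory.dairy_dessert)
    assert a[Requirement.fruit_content].status == expected


def test_no_added_fruit_rule_fails_on_any_fruit():
    p = make_product(name="Carrot puree",
                     ingredients=(("carrot", 94.0), ("apple", 2.0),
                                  ("water", 4.0)))
    a = assess_nutrients(p, Subcategory.vegetable_only_puree)
    assert a[Requirement.fruit_content].status == Status.fail


@pytest.mark.parametrize("sugar,expected", [
    (7.5, HighSugar.warning_required),     # exactly 30% of energy
    (7.49, HighSugar.not_required)])
def test_high_sugar_warning_boundary_inclusive(sugar, expected):
    a = assess_nutrients(_fruit_puree(sugar=sugar, energy=100.0),
                         Subcategory.fruit_puree)
    assert a.high_sugar == expected


def test_added_sugar_requirement_fails_on_lexicon_hit():
    p = make_product(name="Yogurt dessert",
                     ingredients=(("yogurt", 90.0), ("sugar", 10.0)))
    a = assess_nutrients(p, Subcategory.dairy_dessert)
    assert a[Requirement.added_sugar].status == Status.fail
    assert a[Requirement.added_sugar].reason == "lexicon_hit"


def test_cheese_in_name_relaxes_sodium_limit_to_100():
    kw = dict(ingredients=(("rice", 35.0), ("salmon", 25.0),
                           ("green peas", 20.0), ("water", 20.0)),
              sodium=46.0, energy=80.0, texture="chunky")
    plain = make_product(name="Salmon and pea risotto", **kw)
    a = assess_nutrients(plain, Subcategory.chunky_meal_meat_fish_cheese)
    # 57.5 mg/100 kcal exceeds the 50 limit
    assert a[Requirement.sodium].status == Status.fail
    cheesy = make_product(name="Salmon and cheese risotto", **kw)
    b = assess_nutrients(cheesy, Subcategory.chunky_meal_meat_fish_cheese)
    assert b[Requirement.sodium].status == Status.ok


# ---------------------------------------------------------------------------
# missing declarations fail; applicability
# ---------------------------------------------------------------------------

def test_undeclared_panel_fields_fail_with_reason_undeclared():
    p = _no_mf_meal(energy=None, sugar=None, sodium=None, fat=None, protein=None)
    a = assess_nutrients(p, Subcategory.pureed_meal_no_meat_fish)
    for req in (Requirement.energy_density, Requirement.fat,
                Requirement.protein, Requirement.sodium):
        assert a[req].status == Status.fail
        assert a[req].reason == "undeclared"
    assert a.high_sugar == HighSugar.sugar_undeclared
    assert not a.overall_pass


def test_fruit_present_without_percentage_is_undeclared_fail():
    p = make_product(name="Yogurt dessert",
                     ingredients=(("yogurt", 80.0), ("apple", None)))
    a = assess_nutrients(p, Subcategory.dairy_dessert)
    assert a[Requirement.fruit_content].status == Status.fail
    assert a[Requirement.fruit_content].reason == "undeclared"


def test_salt_fallback_feeds_sodium_requirement():
    p = _fruit_puree(sodium=None, salt=0.10, energy=100.0)
    a = assess_nutrients(p, Subcategory.fruit_puree)
    assert a[Requirement.sodium].status == Status.ok
    assert a[Requirement.sodium].measured_value == pytest.approx(40.0)


def test_not_applicable_cells_match_the_profile():
    a = assess_nutrients(_fruit_puree(), Subcategory.fruit_puree)
    assert a[Requirement.protein].status == Status.not_applicable
    assert a[Requirement.fruit_content].status == Status.not_applicable
    chunky = make_product(name="Salmon and pea risotto", texture="chunky",
                          ingredients=(("rice", 40.0), ("salmon", 30.0),
                                       ("water", 30.0)))
    b = assess_nutrients(chunky, Subcategory.chunky_meal_meat_fish_cheese)
    assert b[Requirement.energy_density].status == Status.not_applicable


# ---------------------------------------------------------------------------
# overall pass is the conjunction of the applicable requirements,
# exhaustively over all 2^6 pass/fail combinations
# ---------------------------------------------------------------------------

def _realize(fail_sugar, fail_fruit, fail_energy, fail_fat, fail_protein,
             fail_sodium):
    energy = 45.0 if fail_energy else 80.0
    ingredients = [("carrot", 30.0), ("potato", 28.0), ("water", 26.0),
                   ("lamb", 12.0)]
    if fail_fruit:
        ingredients.append(("apple", 10.0))
    else:
        ingredients.append(("rapeseed oil", 4.0))
    if fail_sugar:
        ingredients[0] = ("carrot", 28.0)
        ingredients.append(("sugar", 2.0))
    fat = (5.0 if fail_fat else 2.0) * energy / 100.0
    protein = (2.0 if fail_protein else 3.6) * energy / 100.0
    sodium = 60.0 if fail_sodium else 10.0
    return make_product(name="Carrot, potato and lamb hotpot",
                        ingredients=tuple(ingredients), energy=energy,
                        fat=fat, protein=protein, sodium=sodium, sugar=1.0)


def test_overall_pass_is_conjunction_over_all_64_combinations():
    reqs = [Requirement.added_sugar, Requirement.fruit_content,
            Requirement.energy_density, Requirement.fat, Requirement.protein,
            Requirement.sodium]
    for flags in itertools.product([False, True], repeat=6):
        a = assess_nutrients(_realize(*flags), Subcategory.pureed_meal_no_meat_fish)
        for req, should_fail in zip(reqs, flags):
            assert (a[req].status == Status.fail) == should_fail, (flags, req)
        assert a.overall_pass == (not any(flags))


def test_high_sugar_never_changes_overall_pass():
    lo = assess_nutrients(_fruit_puree(sugar=1.0, energy=100.0),
                          Subcategory.fruit_puree)
    hi = assess_nutrients(_fruit_puree(sugar=20.0, energy=100.0),
                          Subcategory.fruit_puree)
    assert lo.high_sugar == HighSugar.not_required
    assert hi.high_sugar == HighSugar.warning_required
    assert lo.overall_pass == hi.overall_pass


# ---------------------------------------------------------------------------
# equivalence with an independent straight-line oracle on synthetic products
# ---------------------------------------------------------------------------

_ORACLE_THRESH = {
    # energy_min, (na_kcal, na_g), fat_max, protein_min, named_pct, fruit, high_sugar
    "dairy_dessert": (60, (50, 50), 4.5, None, None, "max5", 40),
    "fruit_puree": (60, (50, 50), 4.5, None, None, None, 30),
    "vegetable_only_puree": (60, (50, 50), 4.5, None, None, "none", 30),
    "vegetable_puree_with_cereal": (60, (50, 50), 4.5, None, None, "none", 20),
    "pureed_meal_cheese": (60, (100, 100), 6, 3, None, "max5", 15),
    "pureed_meal_meat_fish": (60, (50, 50), 6, 4, 10, "max5", 15),
    "pureed_meal_no_meat_fish": (60, (50, 50), 4.5, 3, 8, "max5", 15),
    "chunky_meal_meat_fish_cheese": (None, (50, 50), 6, 4, 10, "max5", 15),
    "chunky_meal_vegetable": (None, (50, 50), 4.5, 3, None, "max5", 15),
}

_FRUIT_NAMES = {"apple", "banana"}
_MEAT_FISH_NAMES = {"chicken", "lamb", "salmon"}


def _oracle_nutrients(p, cat):
    t = _ORACLE_THRESH[cat]
    energy_min, (na_kcal, na_g), fat_max, protein_min, named_pct, fruit, hs = t
    names = [(e.name, e.pct_by_weight) for e in p.ingredients]
    status = {}
    status["added_sugar"] = ("fail" if any(n == "sugar" for n, _ in names)
                             else "pass")
    fruit_pct = sum(w for n, w in names if n in _FRUIT_NAMES)
    if fruit is None:
        status["fruit_content"] = "not_applicable"
    elif fruit == "none":
        status["fruit_content"] = "fail" if fruit_pct > 0 else "pass"
    else:
        status["fruit_content"] = "pass" if fruit_pct <= 5 else "fail"
    e = p.panel.energy_value
    if energy_min is None:
        status["energy_density"] = "not_applicable"
    else:
        status["energy_density"] = ("pass" if e is not None and e >= energy_min
                                    else "fail")
    f = p.panel.total_fat_g
    status["fat"] = ("pass" if e and f is not None and f * 100 / e <= fat_max
                     else "fail")
    pr = p.panel.protein_g
    if protein_min is None:
        status["protein"] = "not_applicable"
    else:
        ok = e and pr is not None and pr * 100 / e >= protein_min
        if ok and named_pct is not None:
            mf = sum(w for n, w in names if n in _MEAT_FISH_NAMES)
            if any(n in _MEAT_FISH_NAMES for n, _ in names):
                ok = mf >= named_pct
        status["protein"] = "pass" if ok else "fail"
    na = p.panel.sodium_mg
    status["sodium"] = ("pass" if e and na is not None
                        and na * 100 / e < na_kcal and na < na_g else "fail")
    s = p.panel.total_sugar_g
    if s is None or not e:
        high = "sugar_undeclared"
    else:
        high = "warning_required" if s * 400 / e >= hs else "not_required"
    overall = all(v != "fail" for v in status.values())
    return status, high, overall


def test_assess_nutrients_matches_straight_line_oracle_on_1000_products():
    products, truths = generate_market(MarketConfig(n_products=1000, seed=202))
    for p, t in zip(products, truths):
        a = assess_nutrients(p, t.subcategory)
        status, high, overall = _oracle_nutrients(p, t.subcategory.value)
        got = {req.value: a[req].status.value for req in Requirement}
        assert got == status, p.product_id
        assert a.high_sugar.value == high
        assert a.overall_pass == overall
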