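"""The six nutrient-composition requirements and the high-sugar warning.

Every product is assessed against: (1) no added sugars/sweeteners,
(2) fruit content, (3) energy density, (4) total fat, (5) protein and
(6) sodium, with per-subcategory thresholds loaded from a versioned
profile.  A product passes the nutrient composition assessment iff it
meets every *applicable* requirement; any product without the nutrient
declarations needed for an applicable requirement fails that requirement
with reason ``undeclared``.

Separately (never part of pass/fail) each product is flagged for a
front-of-pack high-sugar warning when the percentage of energy from
total sugar meets the subcategory threshold (≥40 % dairy desserts,
≥30 % fruit and vegetable-only purées, ≥20 % vegetable purées with
cereals, ≥15 % all meal classes).  Energy from sugar uses the standard
general Atwater factor of 4 kcal/g for carbohydrate; threshold
comparisons follow the printed operators verbatim — ties at '<' limits
fail, ties at '≥'/'≤' limits pass.

If salt is declared instead of sodium, sodium (mg) = salt (g) × 1000 / 2.5.
Energy declared in kJ is converted at 4.184 kJ/kcal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .categorizer import (IngredientLexicon, MEAT_FISH, Subcategory,
                          classify_ingredients, default_lexicon,
                          first_named_food, name_mentions_class)
from .label_model import (EnergyUnit, IngredientClass, NutrientPanel,
                          ProductLabel)
from .sugar_lexicon import SweetenerLexicon, find_added_sugars

KJ_PER_KCAL = 4.184
ATWATER_KCAL_PER_G = {"protein": 4.0, "carbohydrate": 4.0, "fat": 9.0}
SALT_TO_SODIUM_DIVISOR = 2.5


class Requirement(str, enum.Enum):
    added_sugar = "added_sugar"
    fruit_content = "fruit_content"
    energy_density = "energy_density"
    fat = "fat"
    protein = "protein"
    sodium = "sodium"


class Status(str, enum.Enum):
    ok = "pass"
    fail = "fail"
    not_applicable = "not_applicable"


class HighSugar(str, enum.Enum):
    warning_required = "warning_required"
    not_required = "not_required"
    sugar_undeclared = "sugar_undeclared"


class FruitRule(str, enum.Enum):
    max_5pct_weight = "max_5pct_weight"
    no_added_fruit = "no_added_fruit"


@dataclass(frozen=True)
class RequirementResult:
    requirement_id: Requirement
    status: Status
    reason: Optional[str] = None          # threshold_exceeded, undeclared, lexicon_hit, ...
    measured_value: Optional[float] = None
    unit: Optional[str] = None

    @property
    def passed(self) -> bool:
        return self.status == Status.ok

    @property
    def applicable(self) -> bool:
        return self.status != Status.not_applicable


@dataclass(frozen=True)
class ThresholdSet:
    """Thresholds for one subcategory; None marks a non-applicable rule."""
    energy_density_min: Optional[float]
    sodium_max: tuple[float, float]                       # (mg/100 kcal, mg/100 g)
    sodium_max_if_cheese_named: Optional[tuple[float, float]]
    fat_max: float                                        # g/100 kcal
    protein_min: Optional[float]                          # g/100 kcal
    named_protein_min_pct: Optional[float]                # % by weight
    fruit_rule: Optional[FruitRule]
    high_sugar_pct_energy: float


ThresholdTable = dict[Subcategory, ThresholdSet]


def load_profile(path: Optional[str | Path] = None) -> ThresholdTable:
    """Load a threshold profile; the packaged adapted profile by default."""
    if path is None:
        text = (resources.files("cpcf_npm.data") / "npm_profile.yaml").read_text(
            encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    table: ThresholdTable = {}
    for key, t in doc["thresholds"].items():
        table[Subcategory(key)] = ThresholdSet(
            energy_density_min=t["energy_density_min"],
            sodium_max=tuple(t["sodium_max"]),
            sodium_max_if_cheese_named=(tuple(t["sodium_max_if_cheese_named"])
                                        if t["sodium_max_if_cheese_named"] else None),
            fat_max=t["fat_max"],
            protein_min=t["protein_min"],
            named_protein_min_pct=t["named_protein_min_pct"],
            fruit_rule=FruitRule(t["fruit_rule"]) if t["fruit_rule"] else None,
            high_sugar_pct_energy=t["high_sugar_pct_energy"],
        )
    missing = set(Subcategory) - set(table)
    if missing:
        raise ValueError(f"profile missing subcategories: {sorted(m.value for m in missing)}")
    return table


_DEFAULT_TABLE: Optional[ThresholdTable] = None


def default_thresholds() -> ThresholdTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_profile()
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def salt_to_sodium(salt_g: float) -> float:
    """Sodium (mg/100 g) from declared salt (g/100 g): salt / 2.5, in mg."""
    if salt_g < 0:
        raise ValueError(f"salt content must be >= 0, got {salt_g}")
    return salt_g * 1000.0 / SALT_TO_SODIUM_DIVISOR


def energy_kcal_per_100g(panel: NutrientPanel) -> Optional[float]:
    """Declared energy in kcal/100 g, converting kJ at 4.184; None when
    energy is undeclared."""
    if panel.energy_value is None:
        return None
    if panel.energy_unit == EnergyUnit.kJ:
        return panel.energy_value / KJ_PER_KCAL
    return panel.energy_value


def per_100kcal(value_per_100g: Optional[float],
                energy_kcal: Optional[float]) -> Optional[float]:
    """Rescale an amount per 100 g to per 100 kcal; propagates undeclared
    (None) inputs and zero energy as None."""
    if value_per_100g is None or energy_kcal is None or energy_kcal <= 0:
        return None
    return value_per_100g * 100.0 / energy_kcal


def pct_energy_from_sugar(sugar_g: Optional[float],
                          energy_kcal: Optional[float]) -> Optional[float]:
    """% of energy from total sugar at 4 kcal/g; None when undeclared."""
    if sugar_g is None or energy_kcal is None or energy_kcal <= 0:
        return None
    return sugar_g * ATWATER_KCAL_PER_G["carbohydrate"] / energy_kcal * 100.0


def sodium_mg_per_100g(panel: NutrientPanel) -> Optional[float]:
    """Declared sodium, falling back to the salt conversion; sodium takes
    precedence when both are declared."""
    if panel.sodium_mg is not None:
        return panel.sodium_mg
    if panel.salt_g is not None:
        return salt_to_sodium(panel.salt_g)
    return None


# ---------------------------------------------------------------------------
# assessment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NutrientAssessment:
    results: dict[Requirement, RequirementResult]
    overall_pass: bool
    high_sugar: HighSugar

    def __getitem__(self, req: Requirement) -> RequirementResult:
        return self.results[req]


def _na(req: Requirement) -> RequirementResult:
    return RequirementResult(req, Status.not_applicable)


def _undeclared(req: Requirement) -> RequirementResult:
    return RequirementResult(req, Status.fail, reason="undeclared")


def assess_nutrients(p: ProductLabel, cat: Subcategory,
                     thresholds: Optional[ThresholdTable] = None,
                     sweetener_lexicon: Optional[SweetenerLexicon] = None,
                     ingredient_lexicon: Optional[IngredientLexicon] = None,
                     sugar_energy_basis: str = "declared") -> NutrientAssessment:
    """Evaluate the six requirements and the high-sugar warning for one
    categorized product.

    ``sugar_energy_basis`` selects the energy denominator for the
    %-energy-from-sugar computation: ``"declared"`` (default) uses the
    declared energy; ``"atwater"`` recomputes energy from the declared
    macronutrients (protein×4 + fat×9 + sugar×4 — a lower bound, since
    non-sugar carbohydrate is not declared on these panels).
    """
    t = (thresholds or default_thresholds())[cat]
    lex = ingredient_lexicon or default_lexicon()
    classes = classify_ingredients(p.ingredients, lex)
    results: dict[Requirement, RequirementResult] = {}

    # (1) no added sugars/sweeteners — ingredient list is always present
    hits = find_added_sugars(p.ingredients, sweetener_lexicon)
    if hits:
        results[Requirement.added_sugar] = RequirementResult(
            Requirement.added_sugar, Status.fail, reason="lexicon_hit",
            measured_value=float(len(hits)), unit="hits")
    else:
        results[Requirement.added_sugar] = RequirementResult(
            Requirement.added_sugar, Status.ok, measured_value=0.0, unit="hits")

    # (2) fruit content
    fruit_entries = [(e, c) for e, c in zip(p.ingredients, classes)
                     if c == IngredientClass.fruit]
    if t.fruit_rule is None:
        results[Requirement.fruit_content] = _na(Requirement.fruit_content)
    elif t.fruit_rule == FruitRule.no_added_fruit:
        if fruit_entries:
            results[Requirement.fruit_content] = RequirementResult(
                Requirement.fruit_content, Status.fail, reason="fruit_present")
        else:
            results[Requirement.fruit_content] = RequirementResult(
                Requirement.fruit_content, Status.ok, measured_value=0.0, unit="% weight")
    else:  # max_5pct_weight, inclusive
        if not fruit_entries:
            results[Requirement.fruit_content] = RequirementResult(
                Requirement.fruit_content, Status.ok, measured_value=0.0, unit="% weight")
        elif any(e.pct_by_weight is None for e, _ in fruit_entries):
            results[Requirement.fruit_content] = _undeclared(Requirement.fruit_content)
        else:
            fruit_pct = sum(e.pct_by_weight for e, _ in fruit_entries)
            status = Status.ok if fruit_pct <= 5.0 else Status.fail
            results[Requirement.fruit_content] = RequirementResult(
                Requirement.fruit_content, status,
                reason=None if status == Status.ok else "threshold_exceeded",
                measured_value=fruit_pct, unit="% weight")

    energy = energy_kcal_per_100g(p.panel)

    # (3) energy density >= 60 kcal/100 g, inclusive; NA for chunky classes
    if t.energy_density_min is None:
        results[Requirement.energy_density] = _na(Requirement.energy_density)
    elif energy is None:
        results[Requirement.energy_density] = _undeclared(Requirement.energy_density)
    else:
        status = Status.ok if energy >= t.energy_density_min else Status.fail
        results[Requirement.energy_density] = RequirementResult(
            Requirement.energy_density, status,
            reason=None if status == Status.ok else "threshold_exceeded",
            measured_value=energy, unit="kcal/100 g")

    # (4) total fat <= limit g/100 kcal, inclusive
    fat_density = per_100kcal(p.panel.total_fat_g, energy)
    if fat_density is None:
        results[Requirement.fat] = _undeclared(Requirement.fat)
    else:
        status = Status.ok if fat_density <= t.fat_max else Status.fail
        results[Requirement.fat] = RequirementResult(
            Requirement.fat, status,
            reason=None if status == Status.ok else "threshold_exceeded",
            measured_value=fat_density, unit="g/100 kcal")

    # (5) protein — meal classes only
    if t.protein_min is None:
        results[Requirement.protein] = _na(Requirement.protein)
    else:
        results[Requirement.protein] = _assess_protein(p, t, energy, classes, lex)

    # (6) sodium < limit per 100 kcal AND per 100 g, strict
    results[Requirement.sodium] = _assess_sodium(p, t, energy, lex)

    overall = all(r.passed for r in results.values() if r.applicable)

    pct_sugar = _pct_energy_sugar(p.panel, energy, sugar_energy_basis)
    if pct_sugar is None:
        high_sugar = HighSugar.sugar_undeclared
    elif pct_sugar >= t.high_sugar_pct_energy:
        high_sugar = HighSugar.warning_required
    else:
        high_sugar = HighSugar.not_required

    return NutrientAssessment(results=results, overall_pass=overall,
                              high_sugar=high_sugar)


def _pct_energy_sugar(panel: NutrientPanel, declared_energy: Optional[float],
                      basis: str) -> Optional[float]:
    if basis == "declared":
        return pct_energy_from_sugar(panel.total_sugar_g, declared_energy)
    if basis == "atwater":
        if None in (panel.total_sugar_g, panel.total_fat_g, panel.protein_g):
            return None
        energy = (panel.protein_g * ATWATER_KCAL_PER_G["protein"]
                  + panel.total_fat_g * ATWATER_KCAL_PER_G["fat"]
                  + panel.total_sugar_g * ATWATER_KCAL_PER_G["carbohydrate"])
        return pct_energy_from_sugar(panel.total_sugar_g, energy)
    raise ValueError(f"unknown sugar_energy_basis '{basis}'")


def _assess_protein(p: ProductLabel, t: ThresholdSet, energy: Optional[float],
                    classes: list[IngredientClass],
                    lex: IngredientLexicon) -> RequirementResult:
    density = per_100kcal(p.panel.protein_g, energy)
    if density is None:
        return _undeclared(Requirement.protein)
    if density < t.protein_min:
        return RequirementResult(Requirement.protein, Status.fail,
                                 reason="threshold_exceeded",
                                 measured_value=density, unit="g/100 kcal")
    if t.named_protein_min_pct is not None:
        # protein source named in the front-of-pack name must carry enough
        # weight; the named class is read off the product name
        named = first_named_food(p.name, lex)
        if named not in MEAT_FISH:
            named = next((c for _, _, c in lex.matches(p.name) if c in MEAT_FISH),
                         None)
        if named is not None:
            entries = [e for e, c in zip(p.ingredients, classes) if c == named]
            if not entries or any(e.pct_by_weight is None for e in entries):
                return _undeclared(Requirement.protein)
            weight = sum(e.pct_by_weight for e in entries)
            if weight < t.named_protein_min_pct:
                return RequirementResult(
                    Requirement.protein, Status.fail,
                    reason="named_source_below_weight",
                    measured_value=weight, unit="% weight")
    return RequirementResult(Requirement.protein, Status.ok,
                             measured_value=density, unit="g/100 kcal")


def _assess_sodium(p: ProductLabel, t: ThresholdSet, energy: Optional[float],
                   lex: IngredientLexicon) -> RequirementResult:
    sodium = sodium_mg_per_100g(p.panel)
    if sodium is None:
        return _undeclared(Requirement.sodium)
    limits = t.sodium_max
    if (t.sodium_max_if_cheese_named is not None
            and name_mentions_class(p.name, frozenset({IngredientClass.cheese}), lex)):
        limits = t.sodium_max_if_cheese_named
    per_kcal = per_100kcal(sodium, energy)
    if per_kcal is None:
        return _undeclared(Requirement.sodium)
    if per_kcal < limits[0] and sodium < limits[1]:
        return RequirementResult(Requirement.sodium, Status.ok,
                                 measured_value=per_kcal, unit="mg/100 kcal")
    return RequirementResult(Requirement.sodium, Status.fail,
                             reason="threshold_exceeded",
                             measured_value=per_kcal, unit="mg/100 kcal")
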