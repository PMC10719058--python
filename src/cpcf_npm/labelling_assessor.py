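"""The 17 labelling requirements, in five groups, with per-category
applicability.

Groups (5 + 5 + 4 + 2 + 1 = 17):

* protection and promotion of breastfeeding — minimum recommended age of
  introduction ≥6 months; not marketed as suitable for <6 months; a
  message on the importance of breastfeeding to 2 years or beyond; no
  suggestion of superiority/equivalence to breast milk; no promotion of
  bottle feeding;
* claims — no claim in each of the five claim classes (nonpermitted
  compositional, nutrient content, nutrient function, disease risk
  reduction, other);
* product name and ingredient-list clarity — name reflects ingredients
  in descending order; % fruit stated (fruit-containing products only);
  % added water stated (products with water as an ingredient only);
  % protein stated (the four meal classes with a meat/fish/vegetable
  protein focus only);
* messages on products with a spout — a 'do not suck from the container'
  message and a cap-choking-hazard warning (spouted products only);
* age restriction — a maximum recommended age of use of 12 months
  (puréed classes only).

Missing information for an applicable requirement fails that
requirement.  Requirements whose applicability condition is unmet are
``not_applicable`` and excluded from all pass/fail aggregation, so a
group with nothing applicable passes vacuously.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .categorizer import (IngredientLexicon, MEAT_FISH, PUREED_SUBCATEGORIES,
                          Subcategory, classify_ingredients, default_lexicon)
from .label_model import ClaimClass, IngredientClass, ProductLabel
from .nutrient_assessor import RequirementResult, Status


class LabellingRequirement(str, enum.Enum):
    # breastfeeding
    min_age_6mo = "min_age_6mo"
    not_marketed_under_6mo = "not_marketed_under_6mo"
    breastfeeding_2yr_message = "breastfeeding_2yr_message"
    no_superiority_to_breastmilk = "no_superiority_to_breastmilk"
    no_bottle_feeding_promotion = "no_bottle_feeding_promotion"
    # claims
    no_nonpermitted_compositional_claims = "no_nonpermitted_compositional_claims"
    no_nutrient_content_claims = "no_nutrient_content_claims"
    no_nutrient_function_claims = "no_nutrient_function_claims"
    no_disease_risk_reduction_claims = "no_disease_risk_reduction_claims"
    no_other_claims = "no_other_claims"
    # clarity
    name_reflects_ingredient_order = "name_reflects_ingredient_order"
    pct_fruit_stated = "pct_fruit_stated"
    pct_water_stated = "pct_water_stated"
    pct_protein_stated = "pct_protein_stated"
    # spout
    spout_no_suck_message = "spout_no_suck_message"
    spout_choke_warning = "spout_choke_warning"
    # age restriction
    max_age_12mo_stated = "max_age_12mo_stated"


GROUPS: dict[str, tuple[LabellingRequirement, ...]] = {
    "breastfeeding": (
        LabellingRequirement.min_age_6mo,
        LabellingRequirement.not_marketed_under_6mo,
        LabellingRequirement.breastfeeding_2yr_message,
        LabellingRequirement.no_superiority_to_breastmilk,
        LabellingRequirement.no_bottle_feeding_promotion,
    ),
    "claims": (
        LabellingRequirement.no_nonpermitted_compositional_claims,
        LabellingRequirement.no_nutrient_content_claims,
        LabellingRequirement.no_nutrient_function_claims,
        LabellingRequirement.no_disease_risk_reduction_claims,
        LabellingRequirement.no_other_claims,
    ),
    "clarity": (
        LabellingRequirement.name_reflects_ingredient_order,
        LabellingRequirement.pct_fruit_stated,
        LabellingRequirement.pct_water_stated,
        LabellingRequirement.pct_protein_stated,
    ),
    "spout": (
        LabellingRequirement.spout_no_suck_message,
        LabellingRequirement.spout_choke_warning,
    ),
    "age_restriction": (
        LabellingRequirement.max_age_12mo_stated,
    ),
}

# % protein stated applies to the four meal classes with a named protein
# focus; puréed meals with cheese are exempt
_PROTEIN_PCT_CLASSES = frozenset({
    Subcategory.pureed_meal_meat_fish, Subcategory.pureed_meal_no_meat_fish,
    Subcategory.chunky_meal_meat_fish_cheese, Subcategory.chunky_meal_vegetable,
})

_CLAIM_CLASS_TO_REQ = {
    ClaimClass.nonpermitted_compositional: LabellingRequirement.no_nonpermitted_compositional_claims,
    ClaimClass.nutrient_content: LabellingRequirement.no_nutrient_content_claims,
    ClaimClass.nutrient_function: LabellingRequirement.no_nutrient_function_claims,
    ClaimClass.disease_risk_reduction: LabellingRequirement.no_disease_risk_reduction_claims,
    ClaimClass.other: LabellingRequirement.no_other_claims,
}


# ---------------------------------------------------------------------------
# claim classification
# ---------------------------------------------------------------------------

class ClaimLexicon:
    """Ordered pattern lists per claim class; unmatched text → other."""

    def __init__(self, patterns: dict[str, list[str]], order: list[str]):
        self._order = [ClaimClass(c) for c in order]
        self._patterns = {ClaimClass(c): [self._norm(p) for p in pats]
                          for c, pats in patterns.items()}

    @staticmethod
    def _norm(text: str) -> str:
        return re.sub(r"[^a-z0-9%]+", " ", text.lower()).strip()

    @classmethod
    def from_file(cls, path: str | Path) -> "ClaimLexicon":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(doc["patterns"], doc["order"])

    def classify(self, text: str) -> ClaimClass:
        norm = f" {self._norm(text)} "
        for cls in self._order:
            for pat in self._patterns.get(cls, []):
                if f" {pat} " in norm:
                    return cls
        return ClaimClass.other


_DEFAULT_CLAIMS: Optional[ClaimLexicon] = None


def default_claim_lexicon() -> ClaimLexicon:
    global _DEFAULT_CLAIMS
    if _DEFAULT_CLAIMS is None:
        ref = resources.files("cpcf_npm.data") / "claim_lexicon.yaml"
        doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
        _DEFAULT_CLAIMS = ClaimLexicon(doc["patterns"], doc["order"])
    return _DEFAULT_CLAIMS


def classify_claim(text: str, lexicon: Optional[ClaimLexicon] = None) -> ClaimClass:
    """Deterministic single claim class for one claim text."""
    return (lexicon or default_claim_lexicon()).classify(text)


# ---------------------------------------------------------------------------
# assessment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabellingAssessment:
    results: dict[LabellingRequirement, RequirementResult]
    group_pass: dict[str, bool]
    overall_pass: bool

    def __getitem__(self, req: LabellingRequirement) -> RequirementResult:
        return self.results[req]


def _bool_req(req: LabellingRequirement, value: Optional[bool],
              pass_when: bool, fail_reason: str) -> RequirementResult:
    if value is None:
        return RequirementResult(req, Status.fail, reason="undeclared")
    if value == pass_when:
        return RequirementResult(req, Status.ok)
    return RequirementResult(req, Status.fail, reason=fail_reason)


def assess_labelling(p: ProductLabel, cat: Subcategory,
                     claim_lexicon: Optional[ClaimLexicon] = None,
                     ingredient_lexicon: Optional[IngredientLexicon] = None
                     ) -> LabellingAssessment:
    """Evaluate all 17 labelling requirements for one categorized product."""
    f = p.features
    lex = ingredient_lexicon or default_lexicon()
    classes = classify_ingredients(p.ingredients, lex)
    r: dict[LabellingRequirement, RequirementResult] = {}

    # --- breastfeeding ---
    req = LabellingRequirement.min_age_6mo
    if f.min_age_months_stated is None:
        r[req] = RequirementResult(req, Status.fail, reason="undeclared")
    elif f.min_age_months_stated >= 6:
        r[req] = RequirementResult(req, Status.ok,
                                   measured_value=float(f.min_age_months_stated),
                                   unit="months")
    else:
        r[req] = RequirementResult(req, Status.fail, reason="age_below_6_months",
                                   measured_value=float(f.min_age_months_stated),
                                   unit="months")
    r[LabellingRequirement.not_marketed_under_6mo] = _bool_req(
        LabellingRequirement.not_marketed_under_6mo, f.marketed_under_6mo,
        pass_when=False, fail_reason="marketed_under_6mo")
    r[LabellingRequirement.breastfeeding_2yr_message] = _bool_req(
        LabellingRequirement.breastfeeding_2yr_message, f.breastfeeding_2yr_message,
        pass_when=True, fail_reason="message_absent")
    r[LabellingRequirement.no_superiority_to_breastmilk] = _bool_req(
        LabellingRequirement.no_superiority_to_breastmilk,
        f.suggests_superiority_to_breastmilk,
        pass_when=False, fail_reason="superiority_suggested")
    r[LabellingRequirement.no_bottle_feeding_promotion] = _bool_req(
        LabellingRequirement.no_bottle_feeding_promotion,
        f.recommends_bottle_feeding,
        pass_when=False, fail_reason="bottle_feeding_promoted")

    # --- claims: zero claims passes all five ---
    clex = claim_lexicon or default_claim_lexicon()
    present: set[ClaimClass] = set()
    for claim in f.claims:
        cls = claim.claim_class or clex.classify(claim.text)
        present.add(cls)
    for cls, req in _CLAIM_CLASS_TO_REQ.items():
        if cls in present:
            r[req] = RequirementResult(req, Status.fail, reason="claim_present")
        else:
            r[req] = RequirementResult(req, Status.ok)

    # --- clarity ---
    r[LabellingRequirement.name_reflects_ingredient_order] = _bool_req(
        LabellingRequirement.name_reflects_ingredient_order,
        f.name_reflects_ingredient_order,
        pass_when=True, fail_reason="name_order_mismatch")
    has_fruit = IngredientClass.fruit in classes
    req = LabellingRequirement.pct_fruit_stated
    r[req] = (_bool_req(req, f.pct_fruit_stated, True, "pct_not_stated")
              if has_fruit else RequirementResult(req, Status.not_applicable))
    has_water = IngredientClass.water in classes
    req = LabellingRequirement.pct_water_stated
    r[req] = (_bool_req(req, f.pct_water_stated, True, "pct_not_stated")
              if has_water else RequirementResult(req, Status.not_applicable))
    req = LabellingRequirement.pct_protein_stated
    r[req] = (_bool_req(req, f.pct_protein_stated, True, "pct_not_stated")
              if cat in _PROTEIN_PCT_CLASSES
              else RequirementResult(req, Status.not_applicable))

    # --- spout ---
    spouted = f.has_spout is True
    req = LabellingRequirement.spout_no_suck_message
    r[req] = (_bool_req(req, f.spout_no_suck_message, True, "message_absent")
              if spouted else RequirementResult(req, Status.not_applicable))
    req = LabellingRequirement.spout_choke_warning
    r[req] = (_bool_req(req, f.spout_choke_warning, True, "warning_absent")
              if spouted else RequirementResult(req, Status.not_applicable))

    # --- age restriction: puréed classes only ---
    req = LabellingRequirement.max_age_12mo_stated
    r[req] = (_bool_req(req, f.max_age_12mo_stated, True, "max_age_not_stated")
              if cat in PUREED_SUBCATEGORIES
              else RequirementResult(req, Status.not_applicable))

    group_pass = {
        name: all(r[q].passed for q in reqs if r[q].applicable)
        for name, reqs in GROUPS.items()
    }
    overall = all(res.passed for res in r.values() if res.applicable)
    return LabellingAssessment(results=r, group_pass=group_pass,
                               overall_pass=overall)
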