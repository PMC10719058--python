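"""Assigns each purée/meal product to exactly one of nine subcategories.

The subcategory decides which nutrient thresholds and labelling rules
apply.  Classification uses only what is on the label: ingredient
composition (class sums of the stated percentages by weight), the
product name (first named food, cheese mentions) and the texture flag.

Rule precedence (the category definitions are mutually exclusive only
under an ordering; name/meat-fish tests are the most specific and fire
first):

1. texture splits chunky vs puréed;
2. chunky: meat/fish first-named in the product name →
   ``chunky_meal_meat_fish_cheese``, else ``chunky_meal_vegetable``
   (the residual chunky class);
3. puréed, in order: contains meat/fish → meal classes (meat/fish
   first-named → ``pureed_meal_meat_fish``, else
   ``pureed_meal_no_meat_fish``); cheese named in the product name →
   ``pureed_meal_cheese``; dairy the largest class by weight →
   ``dairy_dessert``; ≥95 % vegetables/legumes + water, no fruit, ≤5 %
   everything else → ``vegetable_only_puree``; vegetable/legume/cereal/
   pseudocereal largest with >5 % cereal or pseudocereal →
   ``vegetable_puree_with_cereal``; fruit largest → ``fruit_puree``.

"Largest" compares per-class sums of stated percentages; when any
percentage is missing it falls back to the class of the first-listed
ingredient (labelling convention: descending weight).  The ≥95 % and
>5 % tests require stated percentages and evaluate false otherwise.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .label_model import IngredientClass, IngredientEntry, ProductLabel, Texture

_WORD_RE = re.compile(r"[a-z0-9]+")

MEAT_FISH = frozenset({IngredientClass.meat, IngredientClass.fish})
VEG_LEGUME_WATER = frozenset({IngredientClass.vegetable, IngredientClass.legume,
                              IngredientClass.water})
CEREALS = frozenset({IngredientClass.cereal, IngredientClass.pseudocereal})


class Subcategory(str, enum.Enum):
    dairy_dessert = "dairy_dessert"
    fruit_puree = "fruit_puree"
    vegetable_only_puree = "vegetable_only_puree"
    vegetable_puree_with_cereal = "vegetable_puree_with_cereal"
    pureed_meal_cheese = "pureed_meal_cheese"
    pureed_meal_meat_fish = "pureed_meal_meat_fish"
    pureed_meal_no_meat_fish = "pureed_meal_no_meat_fish"
    chunky_meal_meat_fish_cheese = "chunky_meal_meat_fish_cheese"
    chunky_meal_vegetable = "chunky_meal_vegetable"


PUREED_SUBCATEGORIES = frozenset({
    Subcategory.dairy_dessert, Subcategory.fruit_puree,
    Subcategory.vegetable_only_puree, Subcategory.vegetable_puree_with_cereal,
    Subcategory.pureed_meal_cheese, Subcategory.pureed_meal_meat_fish,
    Subcategory.pureed_meal_no_meat_fish,
})
CHUNKY_SUBCATEGORIES = frozenset({
    Subcategory.chunky_meal_meat_fish_cheese, Subcategory.chunky_meal_vegetable,
})
MEAL_SUBCATEGORIES = frozenset({
    Subcategory.pureed_meal_cheese, Subcategory.pureed_meal_meat_fish,
    Subcategory.pureed_meal_no_meat_fish,
    Subcategory.chunky_meal_meat_fish_cheese, Subcategory.chunky_meal_vegetable,
})


class UncategorizableError(ValueError):
    """Puréed product matching no composition rule."""

    def __init__(self, product_id: str, failed: list[str]):
        self.failed_predicates = failed
        super().__init__(
            f"product '{product_id}' is uncategorizable; failed predicates: "
            + "; ".join(failed))


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------

def _tokens(text: str) -> list[str]:
    return _WORD_RE.findall(text.lower())


class IngredientLexicon:
    """Class → synonym-list lexicon with longest-match lookup.

    Terms are matched as contiguous word sequences on normalised (lower
    case, punctuation-stripped) text, so 'pear' never fires inside
    'pears and apples' tokenised apart, and 'vegetable oil' outranks
    'vegetable'.
    """

    def __init__(self, classes: dict[str, list[str]]):
        # term tuple -> class; longest (most words, then chars) wins
        self._terms: dict[tuple[str, ...], IngredientClass] = {}
        for cls_name, terms in classes.items():
            cls = IngredientClass(cls_name)
            for term in terms:
                key = tuple(_tokens(term))
                if key:
                    self._terms.setdefault(key, cls)
        self._max_len = max((len(k) for k in self._terms), default=1)

    @classmethod
    def from_file(cls, path: str | Path) -> "IngredientLexicon":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(doc["classes"])

    def matches(self, text: str) -> list[tuple[int, tuple[str, ...], IngredientClass]]:
        """All (token position, term, class) matches in reading order,
        keeping only the longest match at each starting position."""
        toks = _tokens(text)
        out = []
        for i in range(len(toks)):
            best: Optional[tuple[tuple[str, ...], IngredientClass]] = None
            for n in range(min(self._max_len, len(toks) - i), 0, -1):
                key = tuple(toks[i:i + n])
                if key in self._terms:
                    best = (key, self._terms[key])
                    break
            if best:
                out.append((i, best[0], best[1]))
        return out

    def classify(self, name: str) -> IngredientClass:
        """Longest-match class for one ingredient name; unclassified when
        no term matches (treated as 'other' in composition sums)."""
        matches = self.matches(name)
        if not matches:
            return IngredientClass.unclassified
        # longest term anywhere in the name wins; ties → earliest position
        _, _, cls = max(matches, key=lambda m: (len(m[1]), sum(map(len, m[1])), -m[0]))
        return cls


_DEFAULT_LEXICON: Optional[IngredientLexicon] = None


def default_lexicon() -> IngredientLexicon:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        ref = resources.files("cpcf_npm.data") / "ingredient_lexicon.yaml"
        doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
        _DEFAULT_LEXICON = IngredientLexicon(doc["classes"])
    return _DEFAULT_LEXICON


def classify_ingredient(name: str,
                        lexicon: Optional[IngredientLexicon] = None) -> IngredientClass:
    """Deterministic ingredient class from longest lexicon match."""
    return (lexicon or default_lexicon()).classify(name)


def first_named_food(product_name: str,
                     lexicon: Optional[IngredientLexicon] = None) -> Optional[IngredientClass]:
    """Class of the first lexicon-matched food token scanning the product
    name left to right; None when no food token is found."""
    matches = (lexicon or default_lexicon()).matches(product_name)
    if not matches:
        return None
    return min(matches, key=lambda m: m[0])[2]


def name_mentions_class(product_name: str, classes: frozenset[IngredientClass],
                        lexicon: Optional[IngredientLexicon] = None) -> bool:
    return any(cls in classes
               for _, _, cls in (lexicon or default_lexicon()).matches(product_name))


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

def classify_ingredients(ingredients: list[IngredientEntry],
                         lexicon: Optional[IngredientLexicon] = None) -> list[IngredientClass]:
    """Resolve each entry's class, using the lexicon for unclassified ones."""
    lex = lexicon or default_lexicon()
    return [e.ingredient_class if e.ingredient_class != IngredientClass.unclassified
            else lex.classify(e.name)
            for e in ingredients]


def _class_weights(ingredients: list[IngredientEntry],
                   classes: list[IngredientClass]) -> Optional[dict[IngredientClass, float]]:
    """Per-class sums of stated percentages; None if any pct is missing."""
    if any(e.pct_by_weight is None for e in ingredients):
        return None
    sums: dict[IngredientClass, float] = {}
    for e, cls in zip(ingredients, classes):
        sums[cls] = sums.get(cls, 0.0) + float(e.pct_by_weight)
    return sums


@dataclass(frozen=True)
class CategoryAssignment:
    """Outcome of categorize(): the subcategory plus the rule that fired."""
    code: Subcategory
    rule: str


def categorize(p: ProductLabel,
               lexicon: Optional[IngredientLexicon] = None) -> CategoryAssignment:
    """Assign exactly one subcategory; see the module docstring for the
    rule precedence.  Raises :class:`UncategorizableError` for a puréed
    product matching no rule."""
    lex = lexicon or default_lexicon()
    classes = classify_ingredients(p.ingredients, lex)
    weights = _class_weights(p.ingredients, classes)
    contains_meat_fish = any(c in MEAT_FISH for c in classes)
    fnf = first_named_food(p.name, lex)

    if p.features.texture == Texture.chunky:
        if fnf in MEAT_FISH:
            return CategoryAssignment(Subcategory.chunky_meal_meat_fish_cheese,
                                      "chunky_meat_fish_first_named")
        return CategoryAssignment(Subcategory.chunky_meal_vegetable,
                                  "chunky_residual")

    # puréed
    if contains_meat_fish:
        if fnf in MEAT_FISH:
            return CategoryAssignment(Subcategory.pureed_meal_meat_fish,
                                      "meat_fish_first_named")
        return CategoryAssignment(Subcategory.pureed_meal_no_meat_fish,
                                  "meat_fish_present_not_first_named")
    if name_mentions_class(p.name, frozenset({IngredientClass.cheese}), lex):
        return CategoryAssignment(Subcategory.pureed_meal_cheese,
                                  "cheese_in_name")

    def class_sum(cs: frozenset[IngredientClass]) -> float:
        assert weights is not None
        return sum(w for c, w in weights.items() if c in cs)

    if weights is not None:
        largest = max(weights, key=lambda c: weights[c])
    else:
        largest = classes[0] if classes else IngredientClass.unclassified

    if largest == IngredientClass.dairy:
        return CategoryAssignment(Subcategory.dairy_dessert, "dairy_largest")

    has_fruit = IngredientClass.fruit in classes
    if (weights is not None and not has_fruit
            and class_sum(VEG_LEGUME_WATER) >= 95.0
            and class_sum(frozenset(set(weights) - VEG_LEGUME_WATER)) <= 5.0):
        return CategoryAssignment(Subcategory.vegetable_only_puree,
                                  "veg_legume_water_95pct")
    if (weights is not None
            and largest in (VEG_LEGUME_WATER | CEREALS) - {IngredientClass.water}
            and class_sum(CEREALS) > 5.0):
        return CategoryAssignment(Subcategory.vegetable_puree_with_cereal,
                                  "veg_cereal_largest_gt5pct_cereal")
    if largest == IngredientClass.fruit:
        return CategoryAssignment(Subcategory.fruit_puree, "fruit_largest")

    raise UncategorizableError(p.product_id, [
        "no meat/fish ingredient",
        "no cheese term in product name",
        "dairy not the largest class",
        "not >=95% vegetables/legumes+water with no fruit",
        "not vegetable/cereal-largest with >5% cereal",
        "fruit not the largest class",
    ])
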