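"""Detection of added sugars and sweeteners in ingredient lists.

The no-added-sugar rule covers four classes: all mono- and
disaccharides (sugar, glucose, fructose, ...), all syrups, nectars and
honey (molasses, agave, maple, malted barley syrup, ...), fruit juices
or concentrated/powdered fruit juice — with lemon and lime juice
explicitly excluded — and nonsugar sweeteners (saccharin, acesulfame,
aspartame, sucralose, stevia, ...).  The model is presence/absence: an
empty hit list means the product passes the requirement.

Intrinsic fruit ("banana") and fruit purée as an ingredient are not
added sugars; fruit purée is governed by the separate fruit-content
requirement.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .label_model import IngredientEntry

_WORD_RE = re.compile(r"[a-z0-9]+")


class SweetenerClass(str, enum.Enum):
    mono_disaccharide = "mono_disaccharide"
    syrup_nectar_honey = "syrup_nectar_honey"
    fruit_juice_or_concentrate = "fruit_juice_or_concentrate"
    nonsugar_sweetener = "nonsugar_sweetener"


@dataclass(frozen=True)
class SweetenerHit:
    ingredient_rank: int          # 1-based position in the ingredient list
    matched_term: str
    sweetener_class: SweetenerClass


class SweetenerLexicon:
    """Term lists per sweetener class plus the juice-word pattern.

    The lemon/lime exclusion overrides any juice match: 'lemon juice
    concentrate' never counts as an added sugar.
    """

    def __init__(self, classes: dict[str, list[str]],
                 juice_words: list[str], juice_exclusions: list[str]):
        self._terms: dict[tuple[str, ...], SweetenerClass] = {}
        for cls_name, terms in classes.items():
            cls = SweetenerClass(cls_name)
            for term in terms:
                key = tuple(_WORD_RE.findall(term.lower()))
                if key:
                    self._terms.setdefault(key, cls)
        self._max_len = max((len(k) for k in self._terms), default=1)
        self._juice_words = frozenset(w.lower() for w in juice_words)
        self._juice_exclusions = frozenset(w.lower() for w in juice_exclusions)

    @classmethod
    def from_file(cls, path: str | Path) -> "SweetenerLexicon":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(doc["classes"], doc.get("juice_words", ["juice"]),
                   doc.get("juice_exclusions", ["lemon", "lime"]))

    def match(self, ingredient_name: str) -> Optional[tuple[str, SweetenerClass]]:
        toks = _WORD_RE.findall(ingredient_name.lower())
        tokset = set(toks)
        # juice pattern: '<fruit> juice', 'concentrated apple juice',
        # 'powdered mango juice', 'apple juice concentrate' ...
        if tokset & self._juice_words and not (tokset & self._juice_exclusions):
            return (ingredient_name.strip(), SweetenerClass.fruit_juice_or_concentrate)
        best: Optional[tuple[tuple[str, ...], SweetenerClass]] = None
        for i in range(len(toks)):
            for n in range(min(self._max_len, len(toks) - i), 0, -1):
                key = tuple(toks[i:i + n])
                if key in self._terms:
                    if best is None or len(key) > len(best[0]):
                        best = (key, self._terms[key])
                    break
        if best is None:
            return None
        return (" ".join(best[0]), best[1])


_DEFAULT: Optional[SweetenerLexicon] = None


def default_sweetener_lexicon() -> SweetenerLexicon:
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("cpcf_npm.data") / "sweetener_lexicon.yaml"
        doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
        _DEFAULT = SweetenerLexicon(doc["classes"], doc.get("juice_words", ["juice"]),
                                    doc.get("juice_exclusions", ["lemon", "lime"]))
    return _DEFAULT


def find_added_sugars(ingredients: list[IngredientEntry],
                      lexicon: Optional[SweetenerLexicon] = None) -> list[SweetenerHit]:
    """One hit per ingredient that matches the sweetener lexicon, in list
    order; an empty list means the no-added-sugar requirement passes."""
    lex = lexicon or default_sweetener_lexicon()
    hits: list[SweetenerHit] = []
    for rank, entry in enumerate(ingredients, start=1):
        m = lex.match(entry.name)
        if m is not None:
            hits.append(SweetenerHit(rank, m[0], m[1]))
    return hits
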