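"""Product-label data model, input/output schema and validation.

The unit of analysis is one unique commercially produced complementary
food (CPCF) purée/meal: everything read off its package — product name,
ordered ingredient list with optional percentages by weight, the nutrient
declaration panel (per 100 g) and the coded label features used by the
labelling assessment.

Two on-disk formats are supported:

* JSON — the lossless canonical format: ``{"schema_version": "1",
  "products": [...]}``.
* CSV — UTF-8, comma-separated; the ingredient list is serialised in a
  single cell as ``;``-separated ``name|pct`` tokens and claims as
  ``;``-separated ``text|class`` tokens.

Nutrient declarations are normalised to per-100 g at ingest.  A record
may declare ``declaration_basis: per_serving`` together with
``serving_size_g``; its panel values are rescaled to 100 g on read.  A
per-serving declaration without a serving size is treated as missing.

Booleans absent from the input stay ``None`` ("unknown"), never silently
``False`` — downstream "missing information fails the requirement" logic
needs the distinction.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pydantic
from pydantic import BaseModel, ConfigDict, Field

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# enums
# ---------------------------------------------------------------------------

class IngredientClass(str, enum.Enum):
    dairy = "dairy"
    fruit = "fruit"
    vegetable = "vegetable"
    legume = "legume"
    cereal = "cereal"
    pseudocereal = "pseudocereal"
    meat = "meat"
    fish = "fish"
    cheese = "cheese"
    water = "water"
    oil_fat = "oil_fat"
    sugar_sweetener = "sugar_sweetener"
    other = "other"
    unclassified = "unclassified"


class EnergyUnit(str, enum.Enum):
    kcal = "kcal"
    kJ = "kJ"


class Texture(str, enum.Enum):
    pureed = "pureed"
    chunky = "chunky"


class ClaimClass(str, enum.Enum):
    nonpermitted_compositional = "nonpermitted_compositional"
    nutrient_content = "nutrient_content"
    nutrient_function = "nutrient_function"
    disease_risk_reduction = "disease_risk_reduction"
    other = "other"


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------
# Range invariants are deliberately NOT enforced at construction time:
# validate_product() reports them as messages and never throws, so the
# models must be able to hold out-of-range values.

class IngredientEntry(BaseModel):
    """One ingredient, carrying its original list position implicitly
    through the order of ``ProductLabel.ingredients`` (1-based rank)."""

    model_config = ConfigDict(use_enum_values=False)

    name: str
    pct_by_weight: Optional[float] = None
    ingredient_class: IngredientClass = IngredientClass.unclassified


class NutrientPanel(BaseModel):
    """Declared nutrient content per 100 g.

    Any field may be missing.  Energy carries a mandatory unit tag when
    present; no silent kJ→kcal conversion happens at read time.  If both
    sodium and salt are declared, sodium takes precedence downstream
    (salt→sodium is the fallback conversion).
    """

    energy_value: Optional[float] = None
    energy_unit: Optional[EnergyUnit] = None
    total_sugar_g: Optional[float] = None
    sodium_mg: Optional[float] = None
    salt_g: Optional[float] = None
    total_fat_g: Optional[float] = None
    protein_g: Optional[float] = None


class Claim(BaseModel):
    text: str
    claim_class: Optional[ClaimClass] = None


class LabelFeatures(BaseModel):
    """Coded label features.

    ``marketed_under_6mo`` and ``recommends_bottle_feeding`` are human-coded
    from label imagery/text; they are inputs, not inferred by the engine.
    Spout messages are only meaningful when ``has_spout`` is true.
    """

    min_age_months_stated: Optional[int] = None
    marketed_under_6mo: Optional[bool] = None
    breastfeeding_2yr_message: Optional[bool] = None
    suggests_superiority_to_breastmilk: Optional[bool] = None
    recommends_bottle_feeding: Optional[bool] = None
    claims: list[Claim] = Field(default_factory=list)
    name_reflects_ingredient_order: Optional[bool] = None
    pct_fruit_stated: Optional[bool] = None
    pct_water_stated: Optional[bool] = None
    pct_protein_stated: Optional[bool] = None
    has_spout: Optional[bool] = None
    spout_no_suck_message: Optional[bool] = None
    spout_choke_warning: Optional[bool] = None
    max_age_12mo_stated: Optional[bool] = None
    texture: Texture = Texture.pureed


class ProductLabel(BaseModel):
    product_id: str
    name: str
    country: Optional[str] = None
    ingredients: list[IngredientEntry] = Field(default_factory=list)
    panel: NutrientPanel = Field(default_factory=NutrientPanel)
    features: LabelFeatures = Field(default_factory=LabelFeatures)


# ---------------------------------------------------------------------------
# validation (pure, never throws)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationMessage:
    code: str
    text: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.text}"


def validate_product(p: ProductLabel) -> list[ValidationMessage]:
    """Check type invariants; empty list iff the record is fully valid."""
    msgs: list[ValidationMessage] = []
    if not p.product_id:
        msgs.append(ValidationMessage("empty_product_id", "product_id must be non-empty"))
    if not p.ingredients:
        msgs.append(ValidationMessage("empty_ingredients", "ingredient list must be non-empty"))
    for rank, ing in enumerate(p.ingredients, start=1):
        if ing.pct_by_weight is not None and not (0.0 <= ing.pct_by_weight <= 100.0):
            msgs.append(ValidationMessage(
                "pct_out_of_range",
                f"ingredient #{rank} '{ing.name}': pct_by_weight {ing.pct_by_weight} outside [0, 100]",
            ))
    panel = p.panel
    for field in ("energy_value", "total_sugar_g", "sodium_mg", "salt_g",
                  "total_fat_g", "protein_g"):
        v = getattr(panel, field)
        if v is not None and v < 0:
            msgs.append(ValidationMessage("negative_nutrient", f"{field} is negative ({v})"))
    if panel.energy_value is not None and panel.energy_unit is None:
        msgs.append(ValidationMessage("missing_energy_unit",
                                      "energy declared without a kcal/kJ unit tag"))
    f = p.features
    if not f.has_spout:
        for field in ("spout_no_suck_message", "spout_choke_warning"):
            if getattr(f, field) is not None:
                msgs.append(ValidationMessage(
                    "spout_message_without_spout",
                    f"{field} set but has_spout is not true"))
    return msgs


# ---------------------------------------------------------------------------
# schema errors
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """Raised on unparseable input; carries the offending row/field."""

    def __init__(self, message: str, row: Optional[int] = None,
                 field: Optional[str] = None):
        self.row = row
        self.field = field
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if field:
            loc.append(f"field '{field}'")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)


# ---------------------------------------------------------------------------
# per-serving normalisation
# ---------------------------------------------------------------------------

def _normalise_basis(raw: dict, row: Optional[int]) -> dict:
    """Rescale per-serving panel values to per-100 g in a raw record dict."""
    basis = raw.pop("declaration_basis", None) or "per_100g"
    serving = raw.pop("serving_size_g", None)
    if basis == "per_100g":
        return raw
    if basis != "per_serving":
        raise SchemaError(f"unknown declaration_basis '{basis}'", row=row,
                          field="declaration_basis")
    panel = raw.get("panel") or {}
    if serving in (None, "", 0):
        # per-serving without a serving size: values are unusable
        raw["panel"] = {}
        return raw
    factor = 100.0 / float(serving)
    scaled = {}
    for k, v in panel.items():
        if k == "energy_unit" or v is None:
            scaled[k] = v
        else:
            scaled[k] = float(v) * factor
    raw["panel"] = scaled
    return raw


def _build_product(raw: dict, row: Optional[int]) -> ProductLabel:
    raw = _normalise_basis(dict(raw), row)
    try:
        return ProductLabel.model_validate(raw)
    except pydantic.ValidationError as e:
        err = e.errors()[0]
        field = ".".join(str(x) for x in err["loc"])
        raise SchemaError(f"schema violation: {err['msg']}", row=row,
                          field=field) from e


# ---------------------------------------------------------------------------
# CSV serialisation helpers
# ---------------------------------------------------------------------------

_CSV_BOOL_FIELDS = [
    "marketed_under_6mo", "breastfeeding_2yr_message",
    "suggests_superiority_to_breastmilk", "recommends_bottle_feeding",
    "name_reflects_ingredient_order", "pct_fruit_stated", "pct_water_stated",
    "pct_protein_stated", "has_spout", "spout_no_suck_message",
    "spout_choke_warning", "max_age_12mo_stated",
]

_CSV_COLUMNS = [
    "product_id", "name", "country", "texture", "ingredients",
    "energy_value", "energy_unit", "total_sugar_g", "sodium_mg", "salt_g",
    "total_fat_g", "protein_g", "declaration_basis", "serving_size_g",
    "min_age_months_stated", *_CSV_BOOL_FIELDS, "claims",
]


def _parse_bool(s: str, row: int, field: str) -> Optional[bool]:
    s = s.strip().lower()
    if s == "":
        return None
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise SchemaError(f"unparseable boolean '{s}'", row=row, field=field)


def _fmt_bool(v: Optional[bool]) -> str:
    return "" if v is None else ("true" if v else "false")


def _parse_float(s: str, row: int, field: str) -> Optional[float]:
    s = s.strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise SchemaError(f"unparseable number '{s}'", row=row, field=field)


def _csv_row_to_raw(rec: dict, row: int) -> dict:
    ingredients = []
    for token in (rec.get("ingredients") or "").split(";"):
        token = token.strip()
        if not token:
            continue
        if "|" in token:
            iname, pct = token.rsplit("|", 1)
            pct_v = _parse_float(pct, row, "ingredients") if pct.strip() else None
        else:
            iname, pct_v = token, None
        ingredients.append({"name": iname.strip(), "pct_by_weight": pct_v})
    claims = []
    for token in (rec.get("claims") or "").split(";"):
        token = token.strip()
        if not token:
            continue
        if "|" in token:
            text, cls = token.rsplit("|", 1)
            claims.append({"text": text.strip(),
                           "claim_class": cls.strip() or None})
        else:
            claims.append({"text": token})
    panel = {
        "energy_value": _parse_float(rec.get("energy_value", ""), row, "energy_value"),
        "energy_unit": (rec.get("energy_unit") or "").strip() or None,
        "total_sugar_g": _parse_float(rec.get("total_sugar_g", ""), row, "total_sugar_g"),
        "sodium_mg": _parse_float(rec.get("sodium_mg", ""), row, "sodium_mg"),
        "salt_g": _parse_float(rec.get("salt_g", ""), row, "salt_g"),
        "total_fat_g": _parse_float(rec.get("total_fat_g", ""), row, "total_fat_g"),
        "protein_g": _parse_float(rec.get("protein_g", ""), row, "protein_g"),
    }
    features: dict = {
        "texture": (rec.get("texture") or "pureed").strip(),
        "claims": claims,
    }
    age = (rec.get("min_age_months_stated") or "").strip()
    features["min_age_months_stated"] = int(age) if age else None
    for field in _CSV_BOOL_FIELDS:
        features[field] = _parse_bool(rec.get(field, ""), row, field)
    raw = {
        "product_id": (rec.get("product_id") or "").strip(),
        "name": rec.get("name") or "",
        "country": (rec.get("country") or "").strip() or None,
        "ingredients": ingredients,
        "panel": panel,
        "features": features,
    }
    basis = (rec.get("declaration_basis") or "").strip()
    if basis:
        raw["declaration_basis"] = basis
        raw["serving_size_g"] = _parse_float(rec.get("serving_size_g", ""),
                                             row, "serving_size_g")
    return raw


def _product_to_csv_row(p: ProductLabel) -> dict:
    ing = ";".join(
        f"{e.name}|{e.pct_by_weight:g}" if e.pct_by_weight is not None else e.name
        for e in p.ingredients)
    claims = ";".join(
        f"{c.text}|{c.claim_class.value}" if c.claim_class is not None else c.text
        for c in p.features.claims)
    row = {
        "product_id": p.product_id,
        "name": p.name,
        "country": p.country or "",
        "texture": p.features.texture.value,
        "ingredients": ing,
        "energy_value": "" if p.panel.energy_value is None else f"{p.panel.energy_value:g}",
        "energy_unit": p.panel.energy_unit.value if p.panel.energy_unit else "",
        "total_sugar_g": "" if p.panel.total_sugar_g is None else f"{p.panel.total_sugar_g:g}",
        "sodium_mg": "" if p.panel.sodium_mg is None else f"{p.panel.sodium_mg:g}",
        "salt_g": "" if p.panel.salt_g is None else f"{p.panel.salt_g:g}",
        "total_fat_g": "" if p.panel.total_fat_g is None else f"{p.panel.total_fat_g:g}",
        "protein_g": "" if p.panel.protein_g is None else f"{p.panel.protein_g:g}",
        "declaration_basis": "",
        "serving_size_g": "",
        "min_age_months_stated": ("" if p.features.min_age_months_stated is None
                                  else str(p.features.min_age_months_stated)),
        "claims": claims,
    }
    for field in _CSV_BOOL_FIELDS:
        row[field] = _fmt_bool(getattr(p.features, field))
    return row


# ---------------------------------------------------------------------------
# public IO
# ---------------------------------------------------------------------------

def read_products(path: str | Path, format: Optional[str] = None) -> list[ProductLabel]:
    """Read and validate product labels from a CSV or JSON file.

    ``format`` defaults to the file extension.  Raises :class:`SchemaError`
    naming field and row on the first unparseable record.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(doc, dict) or "products" not in doc:
            raise SchemaError("JSON document must contain a 'products' list")
        out = []
        for i, raw in enumerate(doc["products"], start=1):
            out.append(_build_product(raw, row=i))
        return out
    if fmt == "csv":
        out = []
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for i, rec in enumerate(reader, start=2):  # 1 = header line
                out.append(_build_product(_csv_row_to_raw(rec, i), row=i))
        return out
    raise SchemaError(f"unknown format '{fmt}'")


def write_products(products: Iterable[ProductLabel], path: str | Path,
                   format: Optional[str] = None) -> None:
    """Write products to CSV or JSON; JSON round-trips losslessly."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    products = list(products)
    if fmt == "json":
        doc = {
            "schema_version": SCHEMA_VERSION,
            "products": [p.model_dump(mode="json", exclude_none=True)
                         for p in products],
        }
        path.write_text(json.dumps(doc, indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
        return
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for p in products:
                writer.writerow(_product_to_csv_row(p))
        return
    raise SchemaError(f"unknown format '{fmt}'")
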