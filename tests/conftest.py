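import pytest

from cpcf_npm import IngredientEntry, LabelFeatures, NutrientPanel, ProductLabel
from cpcf_npm.label_model import EnergyUnit, Texture


def make_product(product_id="p1", name="Apple puree",
                 ingredients=(("apple", 100.0),), texture="pureed",
                 energy=70.0, sugar=5.0, sodium=10.0, salt=None,
                 fat=1.0, protein=1.0, energy_unit="kcal", **features):
    """Product builder with sensible defaults; pass None to drop a panel field."""
    panel = NutrientPanel(
        energy_value=energy,
        energy_unit=EnergyUnit(energy_unit) if energy is not None else None,
        total_sugar_g=sugar, sodium_mg=sodium, salt_g=salt,
        total_fat_g=fat, protein_g=protein)
    feats = LabelFeatures(texture=Texture(texture), **features)
    return ProductLabel(
        product_id=product_id, name=name,
        ingredients=[IngredientEntry(name=n, pct_by_weight=p)
                     for n, p in ingredients],
        panel=panel, features=feats)


@pytest.fixture
def product_factory():
    return make_product
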