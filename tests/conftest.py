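import math

import pytest
import yaml
from importlib.resources import files

from fopscan import ProductRecord, Quantity, default_scheme, default_supply_spec, generate_supply


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def scheme_dict():
    """Raw YAML dict of the shipped scheme — used by the independent oracle
    so that it never goes through the package's scheme model."""
    return yaml.safe_load((files("fopscan") / "data" / "canada2022.yaml").read_text())


def make_product(
    code="P1",
    category="sliced_breads",
    serving=50.0,
    unit="g",
    sodium=0.0,
    saturated_fat=0.0,
    total_sugar=0.0,
    **attrs,
):
    nutrients = {
        "energy": 500.0,
        "total_fat": 2.0,
        "saturated_fat": saturated_fat,
        "total_sugar": total_sugar,
        "fibre": 1.0,
        "protein": 3.0,
        "sodium": sodium,
    }
    return ProductRecord(
        product_code=code,
        category=category,
        serving_size=Quantity(value=serving, unit=unit),
        nutrients_per_serving=nutrients,
        exemption_attributes=attrs,
    )


@pytest.fixture(scope="session")
def small_supply_tables():
    """A reduced synthetic supply (every category, ~15 products each)."""
    spec = default_supply_spec()
    small = spec.model_copy(
        update={
            "categories": tuple(
                c.model_copy(update={"n_products": 15}) for c in spec.categories
            )
        }
    )
    return generate_supply(small, seed=20160901)
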