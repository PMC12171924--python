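"""Seeded synthetic packaged-food supply generator.

The study conditions this emulates: a multi-category label database whose
per-category, per-serving nutrient levels have stated means and SDs;
heavy-tailed (lognormal) sales volumes independent of nutrient content;
and an incomplete label<->sales match (each product appears in the sales
table with probability ``match_probability``, default 0.79).

Nutrient marginals are lognormal, parameterised by method of moments from
the target mean/SD — non-negative and right-skewed, as nutrient contents
are.  An optional equicorrelation is realised through a Gaussian copula.
Everything is reproducible from one master seed via ``SeedSequence``
spawning, so adding a category never perturbs another category's draws.
"""

from __future__ import annotations

import math
from importlib.resources import files
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .catalog import NUTRIENT_UNITS, NUTRIENTS
from .errors import InfeasibleMomentsError
from .rules import RegulatoryScheme, select_tier


class NutrientTarget(BaseModel, frozen=True):
    """Target per-serving mean and SD for one nutrient (canonical units)."""

    mean: float = Field(ge=0)
    sd: float = Field(ge=0)


class AttributeTarget(BaseModel, frozen=True):
    """Normal(mean, sd) target for an exemption attribute, clipped at 0."""

    mean: float
    sd: float = Field(ge=0)


class CategorySpec(BaseModel, frozen=True):
    """Generator parameters for one food category."""

    name: str
    n_products: int = Field(ge=1)
    serving_unit: Literal["g", "mL"] = "g"
    serving_size_choices: tuple[float, ...]
    nutrient_targets: Mapping[str, NutrientTarget]
    correlation: float = 0.0
    sales_lognormal_mu: float = 8.0
    sales_lognormal_sigma: float = 1.4
    match_probability: float = Field(default=0.79, ge=0, le=1)
    exemption_attributes: Mapping[str, AttributeTarget] = Field(default_factory=dict)

    @field_validator("serving_size_choices")
    @classmethod
    def _servings_positive(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if not v or any(s <= 0 for s in v):
            raise ValueError("serving_size_choices must be non-empty and positive")
        return v

    @field_validator("correlation")
    @classmethod
    def _corr_range(cls, v: float) -> float:
        if not 0 <= v < 1:
            raise ValueError(f"correlation must be in [0, 1), got {v}")
        return v

    @field_validator("nutrient_targets")
    @classmethod
    def _all_nutrients(cls, v: Mapping[str, NutrientTarget]) -> Mapping[str, NutrientTarget]:
        missing = set(NUTRIENTS) - set(v)
        if missing:
            raise ValueError(f"nutrient targets missing for {sorted(missing)}")
        return dict(v)


class SupplySpec(BaseModel, frozen=True):
    """A whole synthetic market: one CategorySpec per category."""

    categories: tuple[CategorySpec, ...]

    @model_validator(mode="after")
    def _unique_names(self) -> "SupplySpec":
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise ValueError("category names must be unique")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SupplySpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def default_supply_spec() -> SupplySpec:
    """The shipped 15-category spec (illustrative magnitudes, editable YAML)."""
    text = (files("fopscan") / "data" / "default_supply.yaml").read_text()
    return SupplySpec(**yaml.safe_load(text))


def lognormal_params(mean: float, sd: float, label: str = "value") -> tuple[float, float]:
    """Method-of-moments (mu, sigma) of a lognormal with the given mean/SD.

    sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2/2.  Any positive
    mean admits a fit for any sd >= 0; a zero mean is only feasible as the
    degenerate constant 0.
    """
    if mean < 0 or (mean == 0 and sd > 0):
        raise InfeasibleMomentsError(
            f"{label}: lognormal moments infeasible (mean={mean}, sd={sd})"
        )
    if mean == 0:
        return -math.inf, 0.0  # degenerate: constant zero
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_category(spec: CategorySpec, rng: np.random.Generator, code_prefix: str):
    n = spec.n_products
    servings = rng.choice(np.asarray(spec.serving_size_choices, dtype=float), size=n)

    # Gaussian copula with equicorrelation: shared factor + idiosyncratic part
    rho = spec.correlation
    common = rng.standard_normal(n)
    z = {}
    for nutrient in NUTRIENTS:
        eps = rng.standard_normal(n)
        z[nutrient] = math.sqrt(rho) * common + math.sqrt(1.0 - rho) * eps

    amounts = {}
    for nutrient in NUTRIENTS:
        target = spec.nutrient_targets[nutrient]
        mu, sigma = lognormal_params(target.mean, target.sd, f"{spec.name}/{nutrient}")
        if math.isinf(mu):
            amounts[nutrient] = np.zeros(n)
        elif sigma == 0.0:
            amounts[nutrient] = np.full(n, target.mean)
        else:
            amounts[nutrient] = np.exp(mu + sigma * z[nutrient])

    rows = []
    for i in range(n):
        row = {
            "product_code": f"{code_prefix}{i:05d}",
            "category": spec.name,
            "brand": f"brand_{int(rng.integers(1, 40)):02d}",
            "serving_size": float(servings[i]),
            "serving_unit": spec.serving_unit,
        }
        for nutrient, unit in NUTRIENT_UNITS.items():
            row[f"{nutrient}_{unit.lower()}"] = float(amounts[nutrient][i])
        rows.append(row)
    products = pd.DataFrame(rows)

    for attr, target in spec.exemption_attributes.items():
        draws = np.clip(rng.normal(target.mean, target.sd, size=n), 0.0, None)
        products[f"exemption_{attr}"] = draws

    kg = rng.lognormal(spec.sales_lognormal_mu, spec.sales_lognormal_sigma, size=n)
    price_per_kg = rng.lognormal(math.log(9.0), 0.3, size=n)
    unit_mass_kg = servings * 8.0 / 1000.0  # a pack ~ 8 servings
    matched = rng.random(n) < spec.match_probability
    sales = pd.DataFrame(
        {
            "product_code": products["product_code"],
            "sales_kg": kg,
            "sales_cad": kg * price_per_kg,
            "sales_units": np.maximum(1, np.round(kg / unit_mass_kg)).astype(int),
        }
    )[matched]
    return products, sales


def generate_supply(spec: SupplySpec, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (products table, sales table), CSV-ready, from one seed.

    Each category draws from its own ``SeedSequence`` child stream, so the
    output is fully reproducible and category-local.
    """
    children = np.random.SeedSequence(seed).spawn(len(spec.categories))
    product_frames = []
    sales_frames = []
    for idx, (cat, child) in enumerate(zip(spec.categories, children)):
        rng = np.random.default_rng(child)
        products, sales = _draw_category(cat, rng, code_prefix=f"P{idx:02d}")
        product_frames.append(products)
        sales_frames.append(sales)
    products = pd.concat(product_frames, ignore_index=True)
    sales = pd.concat(sales_frames, ignore_index=True)
    return products, sales


def generate_boundary_fixture(
    scheme: RegulatoryScheme,
    category: str,
    fractions_above_threshold: Sequence[float],
    nutrient: str = "sodium",
    code_prefix: str = "BND",
) -> pd.DataFrame:
    """Products placed at exact relative distances from their flag threshold.

    Product *i* gets ``nutrient`` content at basis equal to
    ``threshold * (1 + f_i)`` — its flag status, and its fate under any
    uniform reduction, is therefore known analytically (f >= 0 flags at
    baseline; a reduction r deflags iff (1 + f)(1 - r) < 1).  Serving size
    is pinned to the reference amount so basis == serving and per-serving
    amounts equal at-basis amounts.  Other nutrients are 0.
    """
    ra = scheme.reference_amount(category)
    tier = select_tier(category, ra, scheme)
    threshold = tier * scheme.daily_values[nutrient]
    rows = []
    for i, f in enumerate(fractions_above_threshold):
        if not -1 < f < 1:
            raise ValueError(f"fraction out of (-1, 1): {f}")
        row = {
            "product_code": f"{code_prefix}{i:04d}",
            "category": category,
            "brand": "fixture",
            "serving_size": ra.value,
            "serving_unit": ra.unit,
        }
        for nut, unit in NUTRIENT_UNITS.items():
            row[f"{nut}_{unit.lower()}"] = 0.0
        unit = NUTRIENT_UNITS[nutrient].lower()
        row[f"{nutrient}_{unit}"] = threshold * (1.0 + f)
        rows.append(row)
    return pd.DataFrame(rows)


def sales_for_products(products: pd.DataFrame, kg: float = 1.0) -> pd.DataFrame:
    """Uniform sales table covering every product (fixture convenience)."""
    return pd.DataFrame(
        {
            "product_code": products["product_code"],
            "sales_kg": kg,
            "sales_cad": kg * 9.0,
            "sales_units": 1,
        }
    )
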