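"""The Canadian front-of-pack "high in" nutrition-symbol classifier.

A packaged food must display the symbol when its content of sodium,
saturated fat or total sugars meets or exceeds a threshold expressed as a
fraction of the nutrient's daily value (DV):

* 15 % of the DV for most foods;
* 30 % for mixed dishes (here frozen meals and pizzas), which are eaten as
  a whole meal;
* 10 % for foods whose regulatory reference amount is at most 30 g (or
  30 mL), i.e. foods eaten in small quantities.

The amount compared against the threshold is the nutrient content in the
*basis amount* — the larger of the label serving size and the category's
reference amount — obtained by linear rescaling of the per-serving
declaration.  Category-level exemptions (e.g. yoghurts with high calcium
content) remove the symbol requirement outright.

Daily values, reference amounts, tier fractions, the small-reference-amount
cutoff, densities and exemption rules are all configuration
(:class:`RegulatoryScheme`), never code: regulation-sourced constants must
be swappable without touching the classifier.
"""

from __future__ import annotations

import hashlib
import json
import math
import operator
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .catalog import MergedSupply, ProductRecord
from .errors import MissingNutrientError, UnknownCategoryError
from .units import Quantity, convert

#: The three nutrients the symbol covers, in reporting order.
CORE_NUTRIENTS: tuple[str, ...] = ("sodium", "saturated_fat", "total_sugar")

_COMPARATORS = {
    ">=": operator.ge,
    ">": operator.gt,
    "<=": operator.le,
    "<": operator.lt,
    "==": operator.eq,
}


class ExemptionRule(BaseModel, frozen=True):
    """Declarative exemption: any matching rule removes the symbol requirement.

    The predicate compares one declared exemption attribute of the product
    (e.g. ``calcium_pct_dv``) against a threshold.  A product missing the
    attribute never matches.
    """

    rule_id: str
    applies_to: frozenset[str]
    attribute: str
    comparator: Literal[">=", ">", "<=", "<", "=="]
    threshold: float

    def matches(self, product: ProductRecord) -> bool:
        if product.category not in self.applies_to:
            return False
        value = product.exemption_attributes.get(self.attribute)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False
        return bool(_COMPARATORS[self.comparator](value, self.threshold))


class TierFractions(BaseModel, frozen=True):
    """DV fractions per threshold tier."""

    default: float = 0.15
    small_reference_amount: float = 0.10
    mixed_dish: float = 0.30

    @field_validator("default", "small_reference_amount", "mixed_dish")
    @classmethod
    def _in_unit_interval(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError(f"tier fraction must be in (0, 1], got {v}")
        return v


class RegulatoryScheme(BaseModel, frozen=True):
    """Everything configurable about the symbol regulation.

    ``small_ra_cutoff`` is interpreted in each category's own reference-
    amount unit (30 g for solids, 30 mL for beverages).  ``densities`` maps
    a category to g/mL, enabling a serving declared in the other unit family
    than the reference amount; without one such a comparison is an error.
    """

    daily_values: Mapping[str, float]
    tier_fractions: TierFractions = TierFractions()
    small_ra_cutoff: float = 30.0
    reference_amounts: Mapping[str, Quantity]
    mixed_dish_categories: frozenset[str] = frozenset()
    densities: Mapping[str, float] = Field(default_factory=dict)
    exemption_rules: tuple[ExemptionRule, ...] = ()

    @field_validator("daily_values")
    @classmethod
    def _dvs(cls, v: Mapping[str, float]) -> Mapping[str, float]:
        for nutrient in CORE_NUTRIENTS:
            if nutrient not in v:
                raise ValueError(f"daily value for '{nutrient}' is required")
            if not v[nutrient] > 0:
                raise ValueError(f"daily value for '{nutrient}' must be > 0")
        return dict(v)

    @model_validator(mode="after")
    def _mixed_registered(self) -> "RegulatoryScheme":
        unknown = self.mixed_dish_categories - set(self.reference_amounts)
        if unknown:
            raise ValueError(f"mixed-dish categories without reference amounts: {sorted(unknown)}")
        return self

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(self.reference_amounts)

    def reference_amount(self, category: str) -> Quantity:
        try:
            return self.reference_amounts[category]
        except KeyError:
            raise UnknownCategoryError(
                f"category {category!r} has no reference amount in the scheme"
            ) from None

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping) -> "RegulatoryScheme":
        data = dict(data)
        ras = {
            cat: Quantity(**q) if isinstance(q, Mapping) else q
            for cat, q in data.get("reference_amounts", {}).items()
        }
        data["reference_amounts"] = ras
        if "exemption_rules" in data:
            data["exemption_rules"] = tuple(
                ExemptionRule(**r) if isinstance(r, Mapping) else r
                for r in data["exemption_rules"]
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegulatoryScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_canonical_dict(self) -> dict:
        data = json.loads(self.model_dump_json())
        # set-valued fields serialise in iteration order; sort for stability
        data["mixed_dish_categories"] = sorted(data["mixed_dish_categories"])
        for rule in data.get("exemption_rules", []):
            rule["applies_to"] = sorted(rule["applies_to"])
        return data

    def content_hash(self) -> str:
        """Stable hash of the scheme content, recorded in run metadata."""
        payload = json.dumps(self.to_canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def scaled(self, factor: float) -> "RegulatoryScheme":
        """Scheme with all daily values multiplied by ``factor`` (testing aid)."""
        return self.model_copy(
            update={"daily_values": {k: v * factor for k, v in self.daily_values.items()}}
        )


def default_scheme() -> RegulatoryScheme:
    """The shipped scheme: Health Canada labelling DVs with illustrative
    per-category reference amounts (editable YAML, not regulation text)."""
    text = (files("fopscan") / "data" / "canada2022.yaml").read_text()
    return RegulatoryScheme.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Classification primitives


def basis_amount(
    serving_size: Quantity,
    reference_amount: Quantity,
    density_g_per_ml: Optional[float] = None,
) -> Quantity:
    """The larger of the label serving size and the reference amount.

    Both quantities must be in the same unit family; a g vs mL comparison
    requires an explicit density.
    """
    serving = convert(serving_size, reference_amount.unit, density_g_per_ml)
    if serving.value >= reference_amount.value:
        return serving
    return reference_amount


def select_tier(category: str, reference_amount: Quantity, scheme: RegulatoryScheme) -> float:
    """DV fraction for a category: mixed dish, small reference amount, or default.

    Branches are evaluated in that order and are exhaustive; the small-
    reference-amount cutoff is inclusive (a 30 g reference amount takes the
    10 % tier).
    """
    if category not in scheme.reference_amounts:
        raise UnknownCategoryError(f"category {category!r} is not registered in the scheme")
    if category in scheme.mixed_dish_categories:
        return scheme.tier_fractions.mixed_dish
    if reference_amount.value <= scheme.small_ra_cutoff:
        return scheme.tier_fractions.small_reference_amount
    return scheme.tier_fractions.default


def amount_at_basis(nutrient_per_serving: float, serving_size: float, basis: float) -> float:
    """Linear rescaling of a per-serving amount to the basis amount."""
    if serving_size <= 0:
        raise ValueError(f"serving size must be > 0, got {serving_size}")
    return nutrient_per_serving * basis / serving_size


@dataclass(frozen=True)
class NutrientAssessment:
    """Audit record for one nutrient: the compared quantities and the outcome."""

    amount_at_basis: float
    threshold: float
    flagged: bool
    missing: bool = False


@dataclass(frozen=True)
class FopVerdict:
    """Classification outcome for one product, with every intermediate kept.

    ``exempted`` implies an empty ``flagged_set``; the per-nutrient
    assessments still record what the comparison would have been.
    """

    product_code: str
    category: str
    tier_fraction: float
    basis: Quantity
    assessments: Mapping[str, NutrientAssessment]
    exempted: bool = False
    exemption_rule_id: Optional[str] = None

    @property
    def flagged_set(self) -> frozenset[str]:
        return frozenset(n for n, a in self.assessments.items() if a.flagged)

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_set)


def classify(
    product: ProductRecord,
    scheme: RegulatoryScheme,
    missing_policy: Literal["strict", "lenient"] = "strict",
) -> FopVerdict:
    """Classify one product against the symbol rules.

    Flagging uses meets-or-exceeds semantics on exact stored values:
    a nutrient is flagged iff ``amount_at_basis >= tier_fraction * DV``.
    Exemption rules are evaluated first and short-circuit to an empty
    flagged set.  A missing core nutrient raises under ``strict`` policy and
    is recorded as unclassifiable (not flagged) under ``lenient``.
    """
    ra = scheme.reference_amount(product.category)
    tier = select_tier(product.category, ra, scheme)
    density = scheme.densities.get(product.category)
    basis = basis_amount(product.serving_size, ra, density)
    serving = convert(product.serving_size, basis.unit, density)

    exemption_id = next(
        (r.rule_id for r in scheme.exemption_rules if r.matches(product)), None
    )
    exempted = exemption_id is not None

    assessments: dict[str, NutrientAssessment] = {}
    for nutrient in CORE_NUTRIENTS:
        threshold = tier * scheme.daily_values[nutrient]
        per_serving = product.nutrient(nutrient)
        if math.isnan(per_serving):
            if missing_policy == "strict":
                raise MissingNutrientError(
                    f"product {product.product_code!r}: missing {nutrient}"
                )
            assessments[nutrient] = NutrientAssessment(
                amount_at_basis=math.nan, threshold=threshold, flagged=False, missing=True
            )
            continue
        at_basis = amount_at_basis(per_serving, serving.value, basis.value)
        flagged = (not exempted) and at_basis >= threshold
        assessments[nutrient] = NutrientAssessment(
            amount_at_basis=at_basis, threshold=threshold, flagged=flagged
        )

    return FopVerdict(
        product_code=product.product_code,
        category=product.category,
        tier_fraction=tier,
        basis=basis,
        assessments=assessments,
        exempted=exempted,
        exemption_rule_id=exemption_id,
    )


def classify_supply(
    supply: MergedSupply | Sequence[ProductRecord],
    scheme: RegulatoryScheme,
    missing_policy: Literal["strict", "lenient"] = "strict",
) -> list[FopVerdict]:
    """One verdict per matched product, in stable supply order."""
    if isinstance(supply, MergedSupply):
        products: Sequence[ProductRecord] = supply.matched_products
    else:
        products = supply
    return [classify(p, scheme, missing_policy) for p in products]


def verdicts_to_frame(verdicts: Iterable[FopVerdict]) -> pd.DataFrame:
    """Flatten verdicts to a tidy frame with every audit intermediate."""
    rows = []
    for v in verdicts:
        row: dict[str, object] = {
            "product_code": v.product_code,
            "category": v.category,
            "tier_fraction": v.tier_fraction,
            "basis_amount": v.basis.value,
            "basis_unit": v.basis.unit,
            "exempted": v.exempted,
            "exemption_rule_id": v.exemption_rule_id or "",
            "n_flagged": v.n_flagged,
        }
        for nutrient, a in v.assessments.items():
            row[f"{nutrient}_at_basis"] = a.amount_at_basis
            row[f"{nutrient}_threshold"] = a.threshold
            row[f"{nutrient}_flagged"] = a.flagged
        rows.append(row)
    return pd.DataFrame(rows)
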