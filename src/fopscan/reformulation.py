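"""Reformulation scenario engine.

A scenario reduces one nutrient of concern (sodium, saturated fat or total
sugar) by a uniform fraction across a category (or the whole supply),
re-classifies every product, and reports the percentage-point (pp) drop in
symbol prevalence.  Reductions act on the per-serving amount; because the
basis rescaling is linear, this is equivalent to reducing the amount at the
basis, and flags for the other nutrients cannot move.

Prevalences in the grid output are percentages (0-100) so that pp changes
read directly in percentage points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import pandas as pd

from .catalog import MergedSupply, ProductRecord
from .rules import CORE_NUTRIENTS, FopVerdict, RegulatoryScheme, classify, classify_supply

#: The reduction grid studied throughout: 5, 10 and 15 %.
DEFAULT_REDUCTIONS: tuple[float, ...] = (0.05, 0.10, 0.15)


@dataclass(frozen=True)
class Scenario:
    """One reformulation scenario: reduce ``target_nutrient`` by ``reduction``.

    ``scope`` restricts the scenario to a category set; ``None`` means all.
    """

    target_nutrient: str
    reduction: float
    scope: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.target_nutrient not in CORE_NUTRIENTS:
            raise ValueError(f"unknown target nutrient {self.target_nutrient!r}")
        if not 0 <= self.reduction < 1:
            raise ValueError(f"reduction must be in [0, 1), got {self.reduction}")

    def applies_to(self, product: ProductRecord) -> bool:
        return self.scope is None or product.category in self.scope


def apply_scenario(product: ProductRecord, scenario: Scenario) -> ProductRecord:
    """Pure transformation: target nutrient x(1 - reduction), all else identical."""
    if not scenario.applies_to(product):
        return product
    amount = product.nutrient(scenario.target_nutrient)
    if math.isnan(amount):
        return product
    return product.with_nutrient(scenario.target_nutrient, amount * (1.0 - scenario.reduction))


def pp_change(before: float, after: float) -> float:
    """Percentage-point drop from ``before`` to ``after`` (both in 0-100)."""
    for v in (before, after):
        if not 0 <= v <= 100:
            raise ValueError(f"percentage out of range: {v}")
    return before - after


def run_scenario_grid(
    supply: MergedSupply | Sequence[ProductRecord],
    scheme: RegulatoryScheme,
    nutrients: Sequence[str] = CORE_NUTRIENTS,
    reductions: Sequence[float] = DEFAULT_REDUCTIONS,
    missing_policy: Literal["strict", "lenient"] = "strict",
) -> pd.DataFrame:
    """Full nutrient x reduction x category grid of symbol prevalence.

    Each row gives, for one category (plus ``overall``), one target
    nutrient and one reduction level (baseline 0 included), the percentage
    of products flagged for that nutrient, alongside the baseline
    percentage and the pp change.  Prevalences are unweighted product
    fractions; exempted products stay exempt under every scenario.
    """
    products = supply.matched_products if isinstance(supply, MergedSupply) else tuple(supply)
    rows = []
    for nutrient in nutrients:
        baseline_by_cat: dict[str, float] = {}
        for reduction in [0.0, *reductions]:
            scenario = Scenario(target_nutrient=nutrient, reduction=reduction)
            verdicts = [classify(apply_scenario(p, scenario), scheme, missing_policy) for p in products]
            groups: dict[str, list[FopVerdict]] = {}
            for v in verdicts:
                groups.setdefault(v.category, []).append(v)
            groups["overall"] = verdicts
            for cat in [*sorted(c for c in groups if c != "overall"), "overall"]:
                vs = groups[cat]
                pct = 100.0 * sum(nutrient in v.flagged_set for v in vs) / len(vs)
                if reduction == 0.0:
                    baseline_by_cat[cat] = pct
                rows.append(
                    {
                        "category": cat,
                        "nutrient": nutrient,
                        "reduction": reduction,
                        "n": len(vs),
                        "prevalence_pct": pct,
                        "baseline_pct": baseline_by_cat[cat],
                        "pp_change": pp_change(baseline_by_cat[cat], pct),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DeflagReduction:
    """Smallest reduction removing a product's flag for one nutrient.

    ``closed_form`` is the exact boundary 1 - threshold/amount_at_basis:
    any reduction strictly above it deflags (meets-or-exceeds flagging
    means the boundary itself still flags).  ``grid_value`` is the smallest
    multiple of ``step`` that deflags, or None when no reduction below
    ``max_reduction`` does.
    """

    closed_form: float
    grid_value: Optional[float]
    step: float

    @property
    def achievable(self) -> bool:
        return self.grid_value is not None


def minimum_deflag_reduction(
    product: ProductRecord,
    scheme: RegulatoryScheme,
    nutrient: str,
    step: float = 0.001,
    max_reduction: float = 0.15,
) -> DeflagReduction:
    """Minimum fractional reduction that removes ``nutrient``'s flag.

    The product must be flagged for the nutrient at baseline.  The grid
    search scans multiples of ``step`` up to ``max_reduction`` (default the
    15 % ceiling of the scenario grid) and re-classifies at each; the
    closed form is reported alongside as an exact cross-check.
    """
    baseline = classify(product, scheme)
    assessment = baseline.assessments.get(nutrient)
    if assessment is None or not assessment.flagged:
        raise ValueError(
            f"product {product.product_code!r} is not flagged for {nutrient} at baseline"
        )
    closed_form = 1.0 - assessment.threshold / assessment.amount_at_basis

    grid_value: Optional[float] = None
    n_steps = int(math.floor(max_reduction / step + 1e-9))
    for k in range(0, n_steps + 1):
        r = k * step
        scenario = Scenario(target_nutrient=nutrient, reduction=r)
        verdict = classify(apply_scenario(product, scenario), scheme)
        if nutrient not in verdict.flagged_set:
            grid_value = r
            break
    return DeflagReduction(closed_form=closed_form, grid_value=grid_value, step=step)
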