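"""Sales-weighted descriptive statistics and symbol-prevalence tables.

Weighting a category mean by sales volume in kg shifts the portrait from
"what is on the shelf" to "what the population buys": a product selling ten
times more contributes ten times the weight.  Symbol prevalences default to
unweighted product fractions (the regulation applies per product), with a
sales-weighted variant available.

All prevalence values returned here are fractions in [0, 1]; reporting
layers multiply by 100.
"""

from __future__ import annotations

import math
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import NUTRIENTS, MergedSupply
from .rules import CORE_NUTRIENTS, FopVerdict


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Sum(w*x)/Sum(w); NaN when the total weight is zero (undefined, not 0)."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        return math.nan
    return float((w * x).sum() / total)


def weighted_sd(values: Sequence[float], weights: Sequence[float]) -> float:
    """Frequency-weight population SD: sqrt(Sum w*(x - x̄_w)^2 / Sum w).

    No reliability correction is applied; the result is invariant to
    rescaling all weights by a constant.  A single observation gives 0.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    mean = weighted_mean(x, w)
    if math.isnan(mean):
        return math.nan
    return float(np.sqrt((w * (x - mean) ** 2).sum() / w.sum()))


def category_summaries(
    supply: MergedSupply,
    weighting: Literal["sales_kg", "unweighted"] = "sales_kg",
    per_100: bool = False,
) -> pd.DataFrame:
    """Per-category nutrient portrait: weighted mean and SD per serving.

    With ``per_100`` the per-serving amounts are first rescaled to
    100 g (or 100 mL) to ease cross-category comparison.
    """
    rows = []
    by_cat: dict[str, list[tuple]] = {}
    for product, sales in supply.matched:
        by_cat.setdefault(product.category, []).append((product, sales))
    for category in sorted(by_cat):
        pairs = by_cat[category]
        weights = [s.sales_kg if weighting == "sales_kg" else 1.0 for _, s in pairs]
        row: dict[str, object] = {"category": category, "n_products": len(pairs)}
        for nutrient in NUTRIENTS:
            values = []
            for p, _ in pairs:
                v = p.nutrient(nutrient)
                if per_100:
                    v = v * 100.0 / p.serving_size.value
                values.append(v)
            row[f"{nutrient}_mean"] = weighted_mean(values, weights)
            row[f"{nutrient}_sd"] = weighted_sd(values, weights)
        rows.append(row)
    return pd.DataFrame(rows)


def _distribution(flag_counts: Sequence[int], weights: Sequence[float]) -> tuple[float, ...]:
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    counts = np.asarray(flag_counts)
    return tuple(float(w[counts == k].sum() / total) for k in range(4))


def prevalence_table(
    verdicts: Sequence[FopVerdict],
    weighting: Literal["unweighted", "sales_kg"] = "unweighted",
    sales_kg_by_code: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Symbol prevalence per category plus an ``overall`` row.

    Columns: ``n``; prevalence fraction per core nutrient; ``any_symbol``;
    ``flagged_0`` .. ``flagged_3`` (distribution of the number of flagged
    nutrients, summing to 1).  Default weighting is unweighted product
    counts; ``sales_kg`` weighting needs ``sales_kg_by_code``.
    """
    if not verdicts:
        raise ValueError("prevalence_table needs at least one verdict")
    if weighting == "sales_kg" and sales_kg_by_code is None:
        raise ValueError("sales_kg weighting requires sales_kg_by_code")

    def weight(v: FopVerdict) -> float:
        if weighting == "unweighted":
            return 1.0
        return float(sales_kg_by_code[v.product_code])  # type: ignore[index]

    groups: dict[str, list[FopVerdict]] = {}
    for v in verdicts:
        groups.setdefault(v.category, []).append(v)

    def summarise(name: str, vs: list[FopVerdict]) -> dict[str, object]:
        w = [weight(v) for v in vs]
        total = sum(w)
        row: dict[str, object] = {"category": name, "n": len(vs)}
        for nutrient in CORE_NUTRIENTS:
            row[nutrient] = (
                sum(wi for v, wi in zip(vs, w) if nutrient in v.flagged_set) / total
            )
        row["any_symbol"] = sum(wi for v, wi in zip(vs, w) if v.n_flagged > 0) / total
        dist = _distribution([v.n_flagged for v in vs], w)
        for k in range(4):
            row[f"flagged_{k}"] = dist[k]
        return row

    rows = [summarise(cat, groups[cat]) for cat in sorted(groups)]
    rows.append(summarise("overall", list(verdicts)))
    return pd.DataFrame(rows)
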