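"""Label database, sales database, and their merge by product code.

The label table holds one row per packaged product with its per-serving
nutrient declaration; the sales table holds scanner sales (kg, CAD$, units)
keyed by the same product codes (UPCs in practice, treated here as opaque
strings).  Matching the two is an exact-key join after code normalisation;
the matched subset is what every sales-weighted statistic downstream uses.

Units are canonicalised once, at load time: sodium is carried in mg, the
mass nutrients in g, energy in kJ.  Nothing downstream converts units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

from .errors import (
    DuplicateProductCodeError,
    MissingColumnError,
    RowValidationError,
)
from .units import Quantity

#: Canonical nutrient keys, in Nutrition Facts order, with canonical units.
NUTRIENT_UNITS: dict[str, str] = {
    "energy": "kJ",
    "total_fat": "g",
    "saturated_fat": "g",
    "total_sugar": "g",
    "fibre": "g",
    "protein": "g",
    "sodium": "mg",
}
NUTRIENTS: tuple[str, ...] = tuple(NUTRIENT_UNITS)

# Accepted CSV column suffixes per nutrient, with the factor that converts
# the column's unit into the canonical one (e.g. a sodium_g column is
# multiplied by 1000 to store mg).
_COLUMN_UNITS: dict[str, dict[str, float]] = {
    "energy": {"kj": 1.0, "kcal": 4.184},
    "sodium": {"mg": 1.0, "g": 1000.0},
    **{n: {"g": 1.0, "mg": 1e-3} for n in ("total_fat", "saturated_fat", "total_sugar", "fibre", "protein")},
}


@dataclass(frozen=True)
class ProductRecord:
    """One labelled product: category, serving declaration, nutrients per serving.

    ``nutrients_per_serving`` maps canonical nutrient keys to amounts in
    canonical units; a value may be NaN when the label omitted it.
    ``exemption_attributes`` carries extra declared values (e.g. calcium %DV)
    consumed only by exemption rules.
    """

    product_code: str
    category: str
    serving_size: Quantity
    nutrients_per_serving: Mapping[str, float]
    brand: str = ""
    exemption_attributes: Mapping[str, float] = field(default_factory=dict)

    def nutrient(self, name: str) -> float:
        return float(self.nutrients_per_serving.get(name, math.nan))

    def with_nutrient(self, name: str, amount: float) -> "ProductRecord":
        """Pure update of one nutrient amount (used by reformulation)."""
        nutrients = dict(self.nutrients_per_serving)
        nutrients[name] = amount
        return replace(self, nutrients_per_serving=nutrients)


@dataclass(frozen=True)
class SalesRecord:
    """Aggregated sales for one product code over the observation window."""

    product_code: str
    sales_kg: float
    sales_cad: float
    sales_units: float


@dataclass(frozen=True)
class MergedSupply:
    """Outcome of the label<->sales join.

    ``matched`` pairs preserve label-table order.  ``unmatched_products``
    stay available for unweighted analyses but are excluded from every
    sales-weighted statistic.
    """

    matched: tuple[tuple[ProductRecord, SalesRecord], ...]
    unmatched_products: tuple[ProductRecord, ...]
    unmatched_sales: tuple[SalesRecord, ...]

    @property
    def unmatched_sales_codes(self) -> tuple[str, ...]:
        return tuple(s.product_code for s in self.unmatched_sales)

    @property
    def matched_products(self) -> tuple[ProductRecord, ...]:
        return tuple(p for p, _ in self.matched)

    @property
    def all_products(self) -> tuple[ProductRecord, ...]:
        return self.matched_products + self.unmatched_products

    def sales_kg_by_code(self) -> dict[str, float]:
        return {s.product_code: s.sales_kg for _, s in self.matched}

    def per_category_counts(self) -> pd.DataFrame:
        """Products and matched products per category (availability table)."""
        rows: dict[str, list[int]] = {}
        for p in self.matched_products:
            rows.setdefault(p.category, [0, 0])[0] += 1
            rows[p.category][1] += 1
        for p in self.unmatched_products:
            rows.setdefault(p.category, [0, 0])[0] += 1
        out = pd.DataFrame(
            [(c, n, m) for c, (n, m) in sorted(rows.items())],
            columns=["category", "n_products", "n_matched"],
        )
        return out


def normalise_code(code: str) -> str:
    """Trim and upper-case a product code (opaque-string semantics)."""
    return str(code).strip().upper()


def _resolve_nutrient_columns(columns: Sequence[str]) -> dict[str, tuple[str, float]]:
    """Map each nutrient to (column name, factor-to-canonical) from the header."""
    resolved: dict[str, tuple[str, float]] = {}
    colset = set(columns)
    for nutrient, options in _COLUMN_UNITS.items():
        for suffix, factor in options.items():
            col = f"{nutrient}_{suffix}"
            if col in colset:
                resolved[nutrient] = (col, factor)
                break
        else:
            raise MissingColumnError(
                f"no column for nutrient '{nutrient}' "
                f"(expected one of {[f'{nutrient}_{s}' for s in options]})"
            )
    return resolved


def load_products(
    path: str | Path,
    on_error: Literal["raise", "collect"] = "raise",
) -> list[ProductRecord] | tuple[list[ProductRecord], list[str]]:
    """Load and validate the label database CSV.

    Required columns: ``product_code, category, serving_size, serving_unit``
    plus one column per nutrient whose suffix declares its unit
    (``sodium_mg`` or ``sodium_g``, ``energy_kj`` or ``energy_kcal``, ...).
    ``brand`` and ``exemption_*`` columns are optional.

    Rows violating invariants (non-positive serving, negative nutrient,
    unknown unit) are never silently dropped: with ``on_error="raise"``
    (default) a :class:`RowValidationError` lists them all; with
    ``"collect"`` the return value is ``(valid_records, error_messages)``.
    """
    df = pd.read_csv(path, dtype={"product_code": str})
    df.columns = [str(c).strip().lower() for c in df.columns]

    for col in ("product_code", "category", "serving_size", "serving_unit"):
        if col not in df.columns:
            raise MissingColumnError(f"required column '{col}' is missing")
    nutrient_cols = _resolve_nutrient_columns(df.columns)
    exemption_cols = [c for c in df.columns if c.startswith("exemption_")]

    records: list[ProductRecord] = []
    errors: list[str] = []
    for row in df.itertuples(index=False):
        r = row._asdict()
        code = normalise_code(r["product_code"])
        try:
            unit = str(r["serving_unit"]).strip()
            if unit not in ("g", "mL"):
                raise ValueError(f"unknown serving unit '{unit}'")
            serving = Quantity(value=float(r["serving_size"]), unit=unit)
            nutrients: dict[str, float] = {}
            for nutrient, (col, factor) in nutrient_cols.items():
                raw = r[col]
                if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                    nutrients[nutrient] = math.nan
                    continue
                amount = float(raw) * factor
                if amount < 0:
                    raise ValueError(f"negative {nutrient} ({raw})")
                nutrients[nutrient] = amount
            attrs = {
                c.removeprefix("exemption_"): float(r[c])
                for c in exemption_cols
                if not (isinstance(r[c], float) and math.isnan(r[c]))
            }
            brand_raw = r.get("brand", "")
            if brand_raw is None or (isinstance(brand_raw, float) and math.isnan(brand_raw)):
                brand_raw = ""
            records.append(
                ProductRecord(
                    product_code=code,
                    category=str(r["category"]).strip(),
                    brand=str(brand_raw),
                    serving_size=serving,
                    nutrients_per_serving=nutrients,
                    exemption_attributes=attrs,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"product {code!r}: {exc}")

    if errors and on_error == "raise":
        raise RowValidationError(errors)
    if on_error == "collect":
        return records, errors
    return records


def write_products(records: Iterable[ProductRecord], path: str | Path) -> None:
    """Write records back to CSV in canonical units (round-trips with loader)."""
    rows = []
    for p in records:
        row: dict[str, object] = {
            "product_code": p.product_code,
            "category": p.category,
            "brand": p.brand,
            "serving_size": p.serving_size.value,
            "serving_unit": p.serving_size.unit,
        }
        for nutrient, unit in NUTRIENT_UNITS.items():
            row[f"{nutrient}_{unit.lower()}"] = p.nutrients_per_serving.get(nutrient, math.nan)
        for attr, value in p.exemption_attributes.items():
            row[f"exemption_{attr}"] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_sales(path: str | Path) -> list[SalesRecord]:
    """Load the sales CSV (one or more rows per product code, not yet aggregated)."""
    df = pd.read_csv(path, dtype={"product_code": str})
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("product_code", "sales_kg", "sales_cad", "sales_units"):
        if col not in df.columns:
            raise MissingColumnError(f"required column '{col}' is missing")
    errors = []
    records = []
    for row in df.itertuples(index=False):
        code = normalise_code(row.product_code)
        kg, cad, units = float(row.sales_kg), float(row.sales_cad), float(row.sales_units)
        if min(kg, cad, units) < 0:
            errors.append(f"sales for {code!r}: negative measure")
            continue
        records.append(SalesRecord(product_code=code, sales_kg=kg, sales_cad=cad, sales_units=units))
    if errors:
        raise RowValidationError(errors)
    return records


def merge_by_code(
    products: Sequence[ProductRecord], sales: Sequence[SalesRecord]
) -> MergedSupply:
    """Exact-key join of label and sales tables on normalised product codes.

    Multiple sales rows for one code are summed first (they are flow
    quantities — period slices of the same product).  Duplicate codes in the
    *label* table are a hard error: the label database must be unique per
    product.
    """
    seen: set[str] = set()
    for p in products:
        code = normalise_code(p.product_code)
        if code in seen:
            raise DuplicateProductCodeError(f"duplicate product code {code!r} in label table")
        seen.add(code)

    aggregated: dict[str, SalesRecord] = {}
    for s in sales:
        code = normalise_code(s.product_code)
        if code in aggregated:
            prev = aggregated[code]
            aggregated[code] = SalesRecord(
                product_code=code,
                sales_kg=prev.sales_kg + s.sales_kg,
                sales_cad=prev.sales_cad + s.sales_cad,
                sales_units=prev.sales_units + s.sales_units,
            )
        else:
            aggregated[code] = SalesRecord(
                product_code=code, sales_kg=s.sales_kg, sales_cad=s.sales_cad, sales_units=s.sales_units
            )

    matched = []
    unmatched = []
    for p in products:
        code = normalise_code(p.product_code)
        rec = aggregated.get(code)
        if rec is None:
            unmatched.append(p)
        else:
            matched.append((p, rec))
    matched_codes = {s.product_code for _, s in matched}
    orphans = tuple(aggregated[c] for c in sorted(set(aggregated) - matched_codes))
    return MergedSupply(
        matched=tuple(matched),
        unmatched_products=tuple(unmatched),
        unmatched_sales=orphans,
    )


@dataclass(frozen=True)
class CoverageReport:
    """Market coverage: share of the labelled supply with matched sales.

    ``per_category`` maps category -> coverage fraction (NaN when undefined);
    ``overall`` is the unweighted mean of the defined per-category coverages
    for the product-count basis, and total-matched-kg / total-sales-kg for
    the sales basis (sales rows for unmatched codes carry no category, so a
    per-category split is undefined there).
    """

    basis: str
    per_category: Mapping[str, float]
    overall: float


def market_coverage(
    supply: MergedSupply, basis: Literal["product_count", "sales_kg"] = "product_count"
) -> CoverageReport:
    if basis == "product_count":
        counts = supply.per_category_counts()
        per_cat = {
            row.category: (row.n_matched / row.n_products if row.n_products else math.nan)
            for row in counts.itertuples()
        }
        defined = [v for v in per_cat.values() if not math.isnan(v)]
        overall = sum(defined) / len(defined) if defined else math.nan
        return CoverageReport(basis=basis, per_category=per_cat, overall=overall)
    if basis == "sales_kg":
        matched_kg = sum(s.sales_kg for _, s in supply.matched)
        total = matched_kg + sum(s.sales_kg for s in supply.unmatched_sales)
        # sales rows for orphan codes carry no category -> per-category undefined
        per_cat = {p.category: math.nan for p, _ in supply.matched}
        overall = math.nan if total == 0 else matched_kg / total
        return CoverageReport(basis=basis, per_category=per_cat, overall=overall)
    raise ValueError(f"unknown coverage basis {basis!r}")
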