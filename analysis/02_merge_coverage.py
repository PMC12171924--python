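#!/usr/bin/env python
"""Merge labels with sales by product code and measure market coverage.

Writes the availability table (products per category, matched counts,
coverage) to results/table1.csv.  Expects 01_generate_supply.py to have
run first.
"""

from pathlib import Path

from fopscan import load_products, load_sales, market_coverage, merge_by_code

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    supply = merge_by_code(
        load_products(ROOT / "scratch" / "products.csv"),
        load_sales(ROOT / "scratch" / "sales.csv"),
    )
    coverage = market_coverage(supply, basis="product_count")
    table1 = supply.per_category_counts()
    table1["coverage"] = table1["category"].map(coverage.per_category)
    (ROOT / "results").mkdir(exist_ok=True)
    table1.to_csv(ROOT / "results" / "table1.csv", index=False)

    n_total = len(supply.all_products)
    print(f"{n_total} products; {len(supply.matched)} cross-referenced with sales")
    print(f"average market coverage (product-count basis): {100 * coverage.overall:.1f}%")
    kg_cov = market_coverage(supply, basis="sales_kg").overall
    print(f"coverage by sales mass: {100 * kg_cov:.1f}%")
    print("wrote results/table1.csv")


if __name__ == "__main__":
    main()
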