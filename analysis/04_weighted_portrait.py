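#!/usr/bin/env python
"""Sales-weighted nutritional portrait of each category.

Writes the per-portion weighted mean +/- SD of all seven declared
nutrients per category to results/table2.csv (and a per-100 g variant for
cross-category comparison).  Weighting is by sales volume in kg, so the
portrait reflects what is bought rather than what is on the shelf.
"""

from pathlib import Path

from fopscan import category_summaries, load_products, load_sales, merge_by_code

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    supply = merge_by_code(
        load_products(ROOT / "scratch" / "products.csv"),
        load_sales(ROOT / "scratch" / "sales.csv"),
    )
    table2 = category_summaries(supply, weighting="sales_kg")
    per100 = category_summaries(supply, weighting="sales_kg", per_100=True)
    (ROOT / "results").mkdir(exist_ok=True)
    table2.to_csv(ROOT / "results" / "table2.csv", index=False)
    per100.to_csv(ROOT / "results" / "table2_per100.csv", index=False)

    top_na = per100.nlargest(3, "sodium_mean")[["category", "sodium_mean"]]
    print("highest sales-weighted sodium per 100 g:")
    for row in top_na.itertuples():
        print(f"  {row.category}: {row.sodium_mean:.0f} mg")
    print("wrote results/table2.csv and results/table2_per100.csv")


if __name__ == "__main__":
    main()
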