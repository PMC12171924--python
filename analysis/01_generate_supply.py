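#!/usr/bin/env python
"""Generate the synthetic 15-category packaged-food supply.

Draws the default label database (~5200 products) and its partially
matched sales table, and writes both CSVs under scratch/ for the later
steps.  The supply emulates a provincial market: lognormal per-serving
nutrient levels per category, heavy-tailed sales volumes, and a ~79 %
label<->sales match rate.
"""

from pathlib import Path

from fopscan import default_supply_spec, generate_supply

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = default_supply_spec()
    products, sales = generate_supply(spec, SEED)
    products.to_csv(OUT / "products.csv", index=False)
    sales.to_csv(OUT / "sales.csv", index=False)
    print(f"generated {len(products)} products in {len(spec.categories)} categories")
    print(f"sales rows: {len(sales)} ({100 * len(sales) / len(products):.1f}% of products)")
    print(f"wrote {OUT / 'products.csv'} and {OUT / 'sales.csv'}")


if __name__ == "__main__":
    main()
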