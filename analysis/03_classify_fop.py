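#!/usr/bin/env python
"""Classify every matched product against the 'high in' symbol rules.

Writes the per-product verdicts (with every audit intermediate: tier,
basis amount, per-nutrient amount/threshold/flag, exemption) to
scratch/verdicts.csv and the prevalence table — share of products flagged
per nutrient and the 0/1/2/3 flagged-nutrient distribution — to
results/fig1.csv, with the stacked-bar rendering at results/fig1.svg.
"""

from pathlib import Path

from fopscan import classify_supply, default_scheme, load_products, load_sales, merge_by_code, prevalence_table
from fopscan.pipeline import render_fig1
from fopscan.rules import verdicts_to_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scheme = default_scheme()
    supply = merge_by_code(
        load_products(ROOT / "scratch" / "products.csv"),
        load_sales(ROOT / "scratch" / "sales.csv"),
    )
    verdicts = classify_supply(supply, scheme)
    verdicts_to_frame(verdicts).to_csv(ROOT / "scratch" / "verdicts.csv", index=False)

    table = prevalence_table(verdicts)
    (ROOT / "results").mkdir(exist_ok=True)
    table.to_csv(ROOT / "results" / "fig1.csv", index=False)
    render_fig1(table, ROOT / "results" / "fig1.svg")

    overall = table.set_index("category").loc["overall"]
    print(f"classified {len(verdicts)} matched products (scheme {scheme.content_hash()})")
    print(
        f"would carry the symbol: {100 * overall['any_symbol']:.0f}% "
        f"(Na {100 * overall['sodium']:.0f}%, sat fat {100 * overall['saturated_fat']:.0f}%, "
        f"sugar {100 * overall['total_sugar']:.0f}%)"
    )
    print(
        "flagged for 1/2/3 nutrients: "
        + " / ".join(f"{100 * overall[f'flagged_{k}']:.1f}%" for k in (1, 2, 3))
    )
    print("wrote results/fig1.csv and results/fig1.svg")


if __name__ == "__main__":
    main()
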