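# fopscan

Surveillance tooling for the Canadian front-of-pack (FoP) **"high in"
nutrition symbol**: given a packaged-food label database and scanner sales
data, it determines which products must carry the symbol, draws
sales-weighted nutritional portraits per food category, and simulates how
modest reformulation (5/10/15 % reductions of sodium, saturated fat or
total sugar) would shift the symbol's prevalence.

It is written for food-supply monitoring groups and public-health nutrition
researchers. Real sales extracts are proprietary, so the package ships a
seeded synthetic supply generator with the same statistical structure
(15 categories, lognormal nutrient levels, heavy-tailed sales, ~79 %
label↔sales match), letting every stage run and be tested end to end
without restricted data.

## The classification rule

A product in category *c* with label serving size *s* and per-serving
nutrient amount *x* is assessed against each nutrient *j* ∈ {Na, sat fat,
total sugars} as follows. With reference amount *RA(c)* (a regulated
typical-consumption quantity), the **basis amount** is

> *B* = max(*s*, *RA(c)*)

and the amount compared is the linear rescaling *x·B/s*. The tier fraction
*t(c)* of the daily value (DV) is

> 0.30 if *c* is a mixed dish (frozen meals, pizzas);
> 0.10 if *RA(c)* ≤ 30 g (or 30 mL);
> 0.15 otherwise,

and the symbol is required for nutrient *j* iff *x·B/s* ≥ *t(c)·DVⱼ*
(meets-or-exceeds), unless a configured exemption applies (e.g. high-calcium
yoghurts). DVs default to sodium 2300 mg, saturated fat 20 g, total sugars
100 g; every constant lives in an editable YAML scheme
(`src/fopscan/data/canada2022.yaml`), not in code.

Category portraits are sales-weighted: mean = Σwᵢxᵢ/Σwᵢ with wᵢ = sales kg,
SD in the frequency-weight population form. A reformulation scenario
multiplies one nutrient by (1−r) everywhere and re-classifies; results are
reported as percentage-point (pp) prevalence changes.

## Worked example

```bash
python analysis/01_generate_supply.py    # synthetic label + sales tables
python analysis/02_merge_coverage.py     # join by product code, coverage
python analysis/03_classify_fop.py       # symbol verdicts + prevalence
python analysis/04_weighted_portrait.py  # sales-weighted nutrient means
python analysis/05_reformulation_grid.py # 5/10/15 % scenario grid
```

prints, among other lines:

```
5190 products; 4148 cross-referenced with sales
average market coverage (product-count basis): 79.8%
would carry the symbol: 69% (Na 45%, sat fat 25%, sugar 18%)
flagged for 1/2/3 nutrients: 50.2% / 18.5% / 0.1%
largest prevalence drops (category, nutrient, reduction -> pp):
  sliced_breads, sodium, -15%: 67% -> 40% (27 pp)
```

Reading: of ~5200 synthetic products, 80 % matched to sales; 69 % of
matched products would carry the symbol, sodium being by far the most
flagged nutrient; and a 15 % sodium reduction in sliced breads would strip
the symbol from 27 pp of that category. Tables land in `results/`
(`table1.csv` availability/coverage, `table2.csv` weighted portrait,
`fig1.csv`+`fig1.svg` flagged-nutrient distribution, `table3.csv` scenario
grid). The same pipeline runs on any real label/sales CSV pair via the CLI:

```bash
fopscan generate --seed 42 --out-products p.csv --out-sales s.csv
fopscan run --products p.csv --sales s.csv --out results/ --seed 42
```

## Layout

- `src/fopscan/` — the library: `catalog` (label/sales I/O and merge),
  `rules` (the symbol classifier), `stats` (weighted portraits,
  prevalence), `reformulation` (scenario engine), `synthetic` (supply
  generator), `pipeline` + `cli` (orchestration and reports).
- `analysis/` — the numbered narrative drivers shown above.
- `docs/methods.md` — modelling assumptions, parameter choices, known
  limitations.
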