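# Methods

## The classifier

The "high in" symbol rule is a pure threshold test per nutrient
(sodium, saturated fat, total sugars): flag iff the nutrient amount in the
*basis amount* meets or exceeds `tier_fraction × daily_value`. The basis
amount is the larger of the label serving size and the category's
reference amount; per-serving amounts are rescaled linearly onto it. Tier
selection is a three-branch decision evaluated in order — mixed dish
(30 %), reference amount ≤ 30 g/30 mL (10 %, boundary inclusive), default
(15 %) — so exactly one tier applies to every product.

Choices the regulation text leaves open, pinned here by tests:

- **Comparator at the threshold is ≥** (meets-or-exceeds). A product
  exactly at `tier × DV` is flagged; one floating-point ulp below is not.
- **No rounding before comparison.** Label-rounding rules are out of
  scope; comparisons use exact stored values.
- **Units are canonicalised once at load time** (sodium mg, mass
  nutrients g, energy kJ — a `sodium_g` CSV column is converted on read).
  Serving-vs-reference comparisons across g/mL require an explicit
  per-category density (g/mL) in the scheme; none is ever assumed.
- **Exemptions are declarative config**, evaluated before the nutrient
  tests; any matching rule empties the flagged set while the verdict keeps
  the would-be comparisons for audit. The shipped rule (yoghurts with
  calcium ≥ 15 % DV) is illustrative.
- **Missing nutrient values**: `strict` policy (default) raises naming the
  product; `lenient` records the nutrient as unclassifiable and leaves it
  unflagged.

All scheme constants ship as editable YAML. The daily values are Health
Canada's labelling DVs (Na 2300 mg, sat fat 20 g, sugars 100 g). The
per-category reference amounts are illustrative defaults of realistic
magnitude: the regulatory Table of Reference Amounts is far more granular
than these 15 surveillance categories, so any single number per category
is a modelling choice, and it is exposed as data for exactly that reason.

## Weighted statistics

Sales weighting uses kg sold: mean `Σwx/Σw`, SD in the frequency-weight
population form `sqrt(Σw(x−x̄)²/Σw)` with no reliability correction — the
weights are measured quantities, not sampling repetitions, and the form is
invariant to rescaling all weights. Zero total weight yields a missing
value, never zero. Nutrient portraits are per label serving ("per
portion"); a per-100 g/mL variant supports cross-category comparison.

Symbol prevalences are **unweighted product fractions** by default (the
regulation applies per product); a sales-weighted variant exists as an
option. Only label↔sales matched products enter weighted statistics;
unmatched products remain available for unweighted analyses.

Market coverage on the product-count basis is the per-category fraction of
labelled products with matched sales, with the overall figure the
unweighted mean of category coverages. A sales-mass basis
(matched kg / total kg) is provided for the overall figure only: orphan
sales codes carry no category, so a per-category split on that basis is
undefined.

## Reformulation scenarios

A scenario multiplies one nutrient's per-serving amount by (1−r),
r ∈ {0.05, 0.10, 0.15}, across a category or the whole supply, and
re-classifies. Because basis rescaling is linear, reducing per-serving and
per-basis amounts are equivalent; flags for non-target nutrients cannot
move, and exempt products stay exempt (reformulation cannot create or
destroy exemptions in this model). Grid prevalences are percentages in
[0, 100] so percentage-point changes read directly; values are rounded
only at presentation.

`minimum_deflag_reduction` reports both the exact boundary
`1 − threshold/amount_at_basis` (any reduction strictly above it deflags,
since the boundary itself still flags under ≥ semantics) and the smallest
multiple of a step (default 0.001) that deflags under actual
re-classification; the two must agree within one step.

## The synthetic supply

The generator emulates the structure the analysis assumes, not any real
market's values:

- **Lognormal nutrient marginals** per category, method-of-moments matched
  to target per-serving mean/SD — non-negative and right-skewed as
  nutrient contents are. A zero-SD target degenerates to a constant; a
  zero mean with positive SD is infeasible and raises naming the nutrient.
  Optional equicorrelation is realised through a Gaussian copula (shared
  normal factor), default off.
- **Heavy-tailed sales**: lognormal kg (default μ=8, σ=1.4), independent
  of nutrient content by default so that weighted and unweighted category
  means estimate the same target; prices ~ lognormal around 9 CAD$/kg.
- **Incomplete matching**: each product enters the sales table with
  probability 0.79, emulating private-label gaps in scanner data.
- **Reproducibility**: one master seed, split per category with
  `SeedSequence.spawn`, so outputs are byte-stable and adding a category
  leaves the others' draws unchanged.

The shipped 15-category spec (~5200 products; cookies and salty snacks the
largest categories) uses per-serving targets chosen once to be realistic
for each category — deli meats and soups sodium-dense, cookies and
flavoured beverages sugar-dense, and so on. What the synthetic supply does
**not** emulate: brand/private-label structure, temporal sales dynamics,
serving-size–nutrient dependence within a category, real inter-nutrient
correlations, or the label-rounding conventions of real Nutrition Facts
tables. Tests passing on it therefore demonstrate the correctness of the
machinery (classification, weighting, scenario arithmetic, determinism) —
not that any real market shows these particular prevalences.

`generate_boundary_fixture` places products at exact relative distances
from their threshold (`threshold × (1+f)`, serving pinned to the reference
amount), making baseline and post-reformulation prevalences analytic; it
backs the exact percentage-point tests and worked examples.

## Numerical and design notes

- Product codes are opaque strings, normalised by trim + upper-case; no
  UPC checksum semantics. Duplicate codes are a hard error in the label
  table and are summed in the sales table (period slices of a flow).
- The pipeline computes all report frames before writing anything, so a
  failing stage leaves no partial outputs; reports carry no timestamps and
  the figure uses a fixed SVG hash salt, making reruns byte-identical.
- Scheme linearity: scaling all DVs and all nutrient amounts by a common
  factor leaves every verdict unchanged (exactly so for power-of-two
  factors in binary floating point).
- Problem sizes in the test suite — 1500 products for the independent
  rules-oracle comparison, 500 random supplies for scenario monotonicity,
  1000 products for the deflag closed-form/grid agreement, 2000 draws for
  generator moment recovery — were chosen to keep the whole suite under a
  minute while leaving comfortable statistical margins.

## Limitations

- Reference amounts and exemption rules are illustrative; conclusions
  about any real category require the regulatory values.
- Energy is carried and summarised but plays no role in classification
  (the Canadian symbol has no energy threshold).
- Uniform fractional reformulation is a deliberately simple counterfactual:
  no substitution effects (sweeteners, potassium salts), no feasibility
  constraints, no consumer-response modelling.
- No inferential statistics are produced; all outputs are descriptive.
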