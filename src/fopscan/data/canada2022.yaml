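# Regulatory scheme for the Canadian front-of-pack "high in" nutrition symbol.
#
# Daily values are Health Canada's labelling DVs. Reference amounts are
# ILLUSTRATIVE per-category defaults of realistic magnitude (the regulatory
# Table of Reference Amounts is category-grained far beyond these 15 groups);
# edit freely — the classifier takes everything from this file.

daily_values:
  sodium: 2300.0        # mg
  saturated_fat: 20.0   # g
  total_sugar: 100.0    # g

tier_fractions:
  default: 0.15
  small_reference_amount: 0.10
  mixed_dish: 0.30

# interpreted in each category's reference-amount unit (30 g / 30 mL)
small_ra_cutoff: 30.0

reference_amounts:
  rte_breakfast_cereals: {value: 40.0, unit: g}
  sliced_breads: {value: 50.0, unit: g}
  luncheon_meats: {value: 55.0, unit: g}
  ready_to_serve_soups: {value: 250.0, unit: g}
  pizzas: {value: 140.0, unit: g}
  granola_bars: {value: 30.0, unit: g}
  frozen_meals: {value: 250.0, unit: g}
  pasta_sauces: {value: 125.0, unit: g}
  yoghurts_dairy_desserts: {value: 175.0, unit: g}
  sausages: {value: 75.0, unit: g}
  cookies: {value: 30.0, unit: g}
  crackers: {value: 20.0, unit: g}
  salty_snacks: {value: 50.0, unit: g}
  processed_cheeses: {value: 30.0, unit: g}
  flavoured_milks_plant_beverages: {value: 250.0, unit: mL}

mixed_dish_categories:
  - frozen_meals
  - pizzas

# g per mL, only needed when a product's serving unit differs from its
# category's reference-amount unit
densities:
  flavoured_milks_plant_beverages: 1.03

# Illustrative exemption: yoghurts with high calcium content keep no symbol.
exemption_rules:
  - rule_id: yoghurt_high_calcium
    applies_to: [yoghurts_dairy_desserts]
    attribute: calcium_pct_dv
    comparator: ">="
    threshold: 15.0
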