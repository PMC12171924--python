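# Default synthetic supply: 15 processed-food categories of the size and
# nutrient magnitude typical of a provincial packaged-food market.
#
# Per-serving nutrient targets (mean, sd) are ILLUSTRATIVE — chosen once to
# be realistic for each category (canonical units: energy kJ, sodium mg,
# everything else g).  Sales volumes are heavy-tailed lognormals;
# match_probability emulates incomplete label<->sales cross-referencing.

categories:
  - name: rte_breakfast_cereals
    n_products: 350
    serving_unit: g
    serving_size_choices: [30, 40, 55]
    nutrient_targets:
      energy: {mean: 600, sd: 150}
      total_fat: {mean: 2.0, sd: 1.5}
      saturated_fat: {mean: 0.5, sd: 0.4}
      total_sugar: {mean: 10.0, sd: 4.5}
      fibre: {mean: 3.0, sd: 2.0}
      protein: {mean: 3.0, sd: 1.5}
      sodium: {mean: 190, sd: 80}

  - name: sliced_breads
    n_products: 300
    serving_unit: g
    serving_size_choices: [45, 50]
    nutrient_targets:
      energy: {mean: 520, sd: 90}
      total_fat: {mean: 2.0, sd: 1.0}
      saturated_fat: {mean: 0.4, sd: 0.3}
      total_sugar: {mean: 3.0, sd: 1.8}
      fibre: {mean: 2.0, sd: 1.0}
      protein: {mean: 4.5, sd: 1.0}
      sodium: {mean: 370, sd: 95}

  - name: luncheon_meats
    n_products: 280
    serving_unit: g
    serving_size_choices: [55]
    nutrient_targets:
      energy: {mean: 450, sd: 120}
      total_fat: {mean: 4.0, sd: 2.5}
      saturated_fat: {mean: 1.5, sd: 1.0}
      total_sugar: {mean: 1.0, sd: 0.8}
      fibre: {mean: 0.2, sd: 0.2}
      protein: {mean: 9.0, sd: 3.0}
      sodium: {mean: 600, sd: 160}

  - name: ready_to_serve_soups
    n_products: 320
    serving_unit: g
    serving_size_choices: [250]
    nutrient_targets:
      energy: {mean: 450, sd: 150}
      total_fat: {mean: 3.0, sd: 2.0}
      saturated_fat: {mean: 1.0, sd: 0.8}
      total_sugar: {mean: 4.0, sd: 2.5}
      fibre: {mean: 1.5, sd: 1.0}
      protein: {mean: 4.0, sd: 2.0}
      sodium: {mean: 650, sd: 140}

  - name: pizzas
    n_products: 260
    serving_unit: g
    serving_size_choices: [120, 140]
    nutrient_targets:
      energy: {mean: 1400, sd: 300}
      total_fat: {mean: 10.0, sd: 3.0}
      saturated_fat: {mean: 7.0, sd: 2.5}
      total_sugar: {mean: 4.0, sd: 2.0}
      fibre: {mean: 2.0, sd: 1.0}
      protein: {mean: 14.0, sd: 4.0}
      sodium: {mean: 720, sd: 190}

  - name: granola_bars
    n_products: 250
    serving_unit: g
    serving_size_choices: [30]
    nutrient_targets:
      energy: {mean: 500, sd: 90}
      total_fat: {mean: 4.0, sd: 1.5}
      saturated_fat: {mean: 1.2, sd: 0.8}
      total_sugar: {mean: 9.0, sd: 3.0}
      fibre: {mean: 1.5, sd: 1.0}
      protein: {mean: 2.0, sd: 1.0}
      sodium: {mean: 85, sd: 40}

  - name: frozen_meals
    n_products: 300
    serving_unit: g
    serving_size_choices: [250, 300]
    nutrient_targets:
      energy: {mean: 1500, sd: 400}
      total_fat: {mean: 9.0, sd: 4.0}
      saturated_fat: {mean: 4.0, sd: 2.5}
      total_sugar: {mean: 6.0, sd: 4.0}
      fibre: {mean: 3.0, sd: 2.0}
      protein: {mean: 18.0, sd: 6.0}
      sodium: {mean: 800, sd: 250}

  - name: pasta_sauces
    n_products: 300
    serving_unit: g
    serving_size_choices: [125]
    nutrient_targets:
      energy: {mean: 300, sd: 100}
      total_fat: {mean: 3.0, sd: 2.0}
      saturated_fat: {mean: 0.8, sd: 0.7}
      total_sugar: {mean: 7.0, sd: 3.0}
      fibre: {mean: 2.0, sd: 1.0}
      protein: {mean: 2.0, sd: 1.0}
      sodium: {mean: 480, sd: 130}

  - name: yoghurts_dairy_desserts
    n_products: 400
    serving_unit: g
    serving_size_choices: [100, 175]
    nutrient_targets:
      energy: {mean: 600, sd: 200}
      total_fat: {mean: 3.0, sd: 2.0}
      saturated_fat: {mean: 1.8, sd: 1.3}
      total_sugar: {mean: 12.0, sd: 6.0}
      fibre: {mean: 0.3, sd: 0.4}
      protein: {mean: 7.0, sd: 3.0}
      sodium: {mean: 80, sd: 40}
    exemption_attributes:
      calcium_pct_dv: {mean: 16.0, sd: 6.0}

  - name: sausages
    n_products: 280
    serving_unit: g
    serving_size_choices: [75, 100]
    nutrient_targets:
      energy: {mean: 900, sd: 250}
      total_fat: {mean: 18.0, sd: 6.0}
      saturated_fat: {mean: 4.5, sd: 2.0}
      total_sugar: {mean: 1.5, sd: 1.0}
      fibre: {mean: 0.2, sd: 0.2}
      protein: {mean: 12.0, sd: 4.0}
      sodium: {mean: 620, sd: 160}

  - name: cookies
    n_products: 700
    serving_unit: g
    serving_size_choices: [30]
    nutrient_targets:
      energy: {mean: 600, sd: 120}
      total_fat: {mean: 6.0, sd: 2.0}
      saturated_fat: {mean: 2.5, sd: 1.2}
      total_sugar: {mean: 12.0, sd: 3.5}
      fibre: {mean: 0.7, sd: 0.5}
      protein: {mean: 1.5, sd: 0.7}
      sodium: {mean: 95, sd: 45}

  - name: crackers
    n_products: 300
    serving_unit: g
    serving_size_choices: [20]
    nutrient_targets:
      energy: {mean: 400, sd: 80}
      total_fat: {mean: 4.0, sd: 1.5}
      saturated_fat: {mean: 0.8, sd: 0.6}
      total_sugar: {mean: 1.5, sd: 1.0}
      fibre: {mean: 0.8, sd: 0.6}
      protein: {mean: 1.5, sd: 0.6}
      sodium: {mean: 140, sd: 55}

  - name: salty_snacks
    n_products: 650
    serving_unit: g
    serving_size_choices: [50]
    nutrient_targets:
      energy: {mean: 1100, sd: 150}
      total_fat: {mean: 15.0, sd: 5.0}
      saturated_fat: {mean: 2.0, sd: 1.5}
      total_sugar: {mean: 2.0, sd: 1.5}
      fibre: {mean: 2.0, sd: 1.0}
      protein: {mean: 3.0, sd: 1.5}
      sodium: {mean: 400, sd: 120}

  - name: processed_cheeses
    n_products: 200
    serving_unit: g
    serving_size_choices: [21, 30]
    nutrient_targets:
      energy: {mean: 350, sd: 80}
      total_fat: {mean: 5.0, sd: 2.0}
      saturated_fat: {mean: 2.8, sd: 1.0}
      total_sugar: {mean: 1.5, sd: 1.0}
      fibre: {mean: 0.0, sd: 0.0}
      protein: {mean: 4.0, sd: 1.5}
      sodium: {mean: 330, sd: 90}

  - name: flavoured_milks_plant_beverages
    n_products: 300
    serving_unit: mL
    serving_size_choices: [250]
    nutrient_targets:
      energy: {mean: 700, sd: 200}
      total_fat: {mean: 3.0, sd: 2.0}
      saturated_fat: {mean: 1.5, sd: 1.2}
      total_sugar: {mean: 20.0, sd: 8.0}
      fibre: {mean: 0.5, sd: 0.5}
      protein: {mean: 6.0, sd: 3.0}
      sodium: {mean: 120, sd: 60}
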