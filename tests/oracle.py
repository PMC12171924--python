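"""Straight-line re-implementation of the 'high in' symbol rules.

Deliberately naive and independent of the fopscan package: it works on
plain dicts and the raw scheme YAML mapping, transcribing the rule text
directly.  Used only as a cross-check oracle in tests.
"""


def naive_flags(product: dict, scheme: dict) -> tuple[set, bool]:
    """Return (flagged nutrient set, exempted) for one product dict.

    ``product`` keys: category, serving_size, serving_unit,
    sodium/saturated_fat/total_sugar per serving in canonical units,
    optional attrs dict.
    """
    cat = product["category"]
    ra = scheme["reference_amounts"][cat]
    ra_value, ra_unit = float(ra["value"]), ra["unit"]

    serving = float(product["serving_size"])
    if product["serving_unit"] != ra_unit:
        density = scheme["densities"][cat]
        serving = serving * density if product["serving_unit"] == "mL" else serving / density

    # The highest amount between the serving size and the reference amount
    basis = serving if serving > ra_value else ra_value

    # 30% of DV for mixed dishes; 10% when the reference amount is <= 30 g
    # (or mL); 15% for most products.
    if cat in scheme["mixed_dish_categories"]:
        tier = scheme["tier_fractions"]["mixed_dish"]
    elif ra_value <= scheme["small_ra_cutoff"]:
        tier = scheme["tier_fractions"]["small_reference_amount"]
    else:
        tier = scheme["tier_fractions"]["default"]

    exempted = False
    for rule in scheme.get("exemption_rules", []):
        if cat not in rule["applies_to"]:
            continue
        value = product.get("attrs", {}).get(rule["attribute"])
        if value is None:
            continue
        op = rule["comparator"]
        thr = rule["threshold"]
        hit = (
            (op == ">=" and value >= thr)
            or (op == ">" and value > thr)
            or (op == "<=" and value <= thr)
            or (op == "<" and value < thr)
            or (op == "==" and value == thr)
        )
        if hit:
            exempted = True

    flags = set()
    if not exempted:
        for nutrient in ("sodium", "saturated_fat", "total_sugar"):
            at_basis = float(product[nutrient]) * basis / serving
            if at_basis >= tier * scheme["daily_values"][nutrient]:
                flags.add(nutrient)
    return flags, exempted
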