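# Default constraint set: EFSA-2017-style, illustrative.
#
# The authoritative dietary reference values live in the EFSA DRV
# publications and are not bundled; this shipped default carries a
# representative adult (25-49 y) set so the pipeline runs end to end.
# Replace this file for a faithful national application.
#
# Units: g/day, mg/day, µg/day are taken literally; %energy is converted
# to grams via the EC 90/496/EEC energy factors below and the reference
# person's recommended energy intake; g/kg-bodyweight multiplies the
# reference body weight; mg/MJ multiplies the recommended MJ/day.

energy_factors_kj_per_g:
  protein: 17
  carbohydrate: 17
  fat: 37
  fibre: 8
  alcohol: 29

constraints:
  - {id: protein_lower, target: protein_g, bound: lower, value: 0.83, unit: g/kg-bodyweight}
  - {id: fat_lower, target: fat_g, bound: lower, value: 20, unit: "%energy"}
  - {id: fat_upper, target: fat_g, bound: upper, value: 35, unit: "%energy"}
  - {id: satfat_upper, target: satfat_g, bound: upper, value: 10, unit: "%energy"}
  - {id: pufa_lower, target: pufa_g, bound: lower, value: 4, unit: "%energy"}
  - {id: cholesterol_upper, target: cholesterol_mg, bound: upper, value: 300, unit: mg/day}
  - {id: carb_lower, target: carb_g, bound: lower, value: 45, unit: "%energy"}
  - {id: carb_upper, target: carb_g, bound: upper, value: 60, unit: "%energy"}
  - {id: free_sugars_upper, target: free_sugars_g, bound: upper, value: 10, unit: "%energy"}
  - {id: fibre_lower, target: fibre_g, bound: lower, value: 25, unit: g/day}
  - {id: salt_upper, target: salt_g, bound: upper, value: 6, unit: g/day}
  - {id: vitamin_c_lower_m, target: vitamin_c_mg, bound: lower, value: 110, unit: mg/day, applies_to: man}
  - {id: vitamin_c_lower_w, target: vitamin_c_mg, bound: lower, value: 95, unit: mg/day, applies_to: woman}
  # Vitamin D can also be produced endogenously; a 5 µg/day floor is used
  # instead of the full dietary reference value.
  - {id: vitamin_d_lower, target: vitamin_d_ug, bound: lower, value: 5, unit: µg/day}
  - {id: vitamin_b12_lower, target: vitamin_b12_ug, bound: lower, value: 4, unit: µg/day}
  - {id: folate_lower, target: folate_ug, bound: lower, value: 330, unit: µg/day}
  - {id: calcium_lower, target: calcium_mg, bound: lower, value: 950, unit: mg/day}
  - {id: iron_lower_m, target: iron_mg, bound: lower, value: 11, unit: mg/day, applies_to: man}
  - {id: iron_lower_w, target: iron_mg, bound: lower, value: 16, unit: mg/day, applies_to: woman}
  - {id: magnesium_lower_m, target: magnesium_mg, bound: lower, value: 350, unit: mg/day, applies_to: man}
  - {id: magnesium_lower_w, target: magnesium_mg, bound: lower, value: 300, unit: mg/day, applies_to: woman}
  - {id: potassium_lower, target: potassium_mg, bound: lower, value: 3500, unit: mg/day}
  - {id: zinc_lower_m, target: zinc_mg, bound: lower, value: 9.4, unit: mg/day, applies_to: man}
  - {id: zinc_lower_w, target: zinc_mg, bound: lower, value: 7.5, unit: mg/day, applies_to: woman}

food_rules:
  # Total energy is anchored at the recommended intake rE (band 0 = equality).
  energy:
    band_fraction: 0.0
  # Fruits and vegetables must provide 7-14 % of energy, converted to grams
  # using a mean caloric density of 2 fruit portions at 50 kcal/100 g and
  # 3 vegetable portions at 20 kcal/100 g (weighted mean 32 kcal/100 g).
  fruit_veg:
    lower_pct_energy: 7
    upper_pct_energy: 14
    portions: {fruits: 2, vegetables: 3}
    portion_kcal_per_100g: {fruits: 50, vegetables: 20}
    categories: [fruits, vegetables]
  # Water from beverages and food; the upper bound caps beverages at 30 %
  # above the recommended amount so they are not over-represented.
  water:
    recommended_g_day: {man: 2500, woman: 2000}
    upper_multiplier: 1.3
  # Caffeine is modelled as a mass cap on coffee and tea: 400 mg/day safe
  # intake at just under 100 mg per 200-ml cup gives 4 cups (800 g) for the
  # reference man; the woman's cap is scaled by the body-weight ratio.
  caffeine:
    safe_mg_day: 400
    mg_per_cup: 100
    cup_g: 200
    codes: ["01.2.1.1", "01.2.1.2"]
    scale_woman_by_bodyweight: true
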