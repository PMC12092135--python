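# Housing-temperature x dietary-salt treatment cells for the captive
# deer-mouse study design, with group-mean (+/- SD) metabolic rates.
# The two cooler housing temperatures (18 and 15 C) yielded similar data
# and are pooled; the pooled cell is parameterized at 18 C / 60 % rh.
# Diet compositions are mass fractions of the two chows; ingredient
# entries are [cellulose d18O permil, diet weight fraction].
diets:
  lowsalt:
    f_carb: 0.672
    f_protein: 0.254
    f_fat: 0.074
    ingredients:
      corn: [26.0, 0.43]
      wheat: [26.9, 0.37]
      soybean: [25.9, 0.20]
  highsalt:
    f_carb: 0.658
    f_protein: 0.265
    f_fat: 0.077
    ingredients:
      corn: [26.0, 0.39]
      wheat: [26.9, 0.39]
      soybean: [25.9, 0.22]
# Ambient-vapour d18O varies with sampling month (regional isoscape):
food_d18O_by_month:
  may: -18.16
  june: -16.41
  july: -16.35
treatments:
  lowsalt_25C:
    diet: lowsalt
    ambient_temp_C: 25
    rel_humidity: 0.45
    window_hours: 96
    food_d18O: -16.41
    n_mice: 6
    o2_ml_min: [0.95, 0.23]
    rq: [0.87, 0.01]
    food_g_day: [3.48, 1.49]
    water_ml_day: [2.42, 0.40]
    body_mass_g: [19.19, 1.17]
  lowsalt_cold:
    diet: lowsalt
    ambient_temp_C: 18
    rel_humidity: 0.60
    window_hours: 96
    food_d18O: -16.41
    n_mice: 6
    o2_ml_min: [1.33, 0.19]
    rq: [0.88, 0.01]
    food_g_day: [4.00, 0.70]
    water_ml_day: [2.86, 0.36]
    body_mass_g: [19.96, 1.01]
  highsalt_25C:
    diet: highsalt
    ambient_temp_C: 25
    rel_humidity: 0.45
    window_hours: 48
    food_d18O: -16.41
    n_mice: 8
    o2_ml_min: [0.96, 0.12]
    rq: [0.80, 0.03]
    food_g_day: [3.14, 1.35]
    water_ml_day: [5.60, 1.29]
    body_mass_g: [19.12, 0.98]
  highsalt_cold:
    diet: highsalt
    ambient_temp_C: 18
    rel_humidity: 0.60
    window_hours: 48
    food_d18O: -16.41
    n_mice: 8
    o2_ml_min: [1.39, 0.18]
    rq: [0.87, 0.03]
    food_g_day: [4.48, 0.98]
    water_ml_day: [6.19, 0.74]
    body_mass_g: [19.62, 1.28]
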