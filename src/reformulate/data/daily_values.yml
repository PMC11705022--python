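# Daily Value reference amounts used as denominators for the
# reformulation thresholds (5 % DV = "a little", 15 % DV = "a lot").
# Transcribed from Health Canada's Table of Daily Values (2016 revision,
# adults and children >= 4 years).  Carbohydrate and protein carry the
# long-standing 2000 kcal reference-diet amounts (300 g and 50 g); the
# 2016 table assigns them no DV.  Units match the per-100 nutrient
# fields: kcal, g, mg.
version: health-canada-dv-2016/r1
values:
  energy_kcal: 2000
  fat_g: 75
  satfat_g: 20
  carb_g: 300
  sugars_g: 100
  protein_g: 50
  sodium_mg: 2300
  fibre_g: 28
  calcium_mg: 1300
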