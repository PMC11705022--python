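# Nutrient Profiling Scoring Criterion point tables, transcribed from
# the FSANZ Food Standards Code (Standard 1.2.7 / Schedule 4).  All
# thresholds apply per 100 g (or 100 ml for beverages).  Each step means
# "score these points when the value exceeds the threshold"; comparison
# is strict (gt) unless marked ge.  The scorer is entirely table-driven:
# edit this file, not code, to track revisions of the standard.
version: fsanz-npsc-schedule4/r1
kj_per_kcal: 4.184

# Score thresholds for health-claim eligibility (score strictly below
# the bound passes the NPSC).
categories:
  cat1: {label: beverages, pass_below: 1}
  cat2: {label: other foods, pass_below: 4}
  cat3: {label: cheese, edible oils, spreads, margarine, butter, pass_below: 28}

# Protein points are withheld when baseline points reach the gate unless
# the food scores enough fvnl (V) points; category 3 foods are exempt.
protein_gate:
  baseline_at_least: 13
  v_points_waiver: 5
  exempt_categories: [cat3]

baseline_components:
  energy_kj:
    max_points: 10
    steps:
      - {gt: 335, points: 1}
      - {gt: 670, points: 2}
      - {gt: 1005, points: 3}
      - {gt: 1340, points: 4}
      - {gt: 1675, points: 5}
      - {gt: 2010, points: 6}
      - {gt: 2345, points: 7}
      - {gt: 2680, points: 8}
      - {gt: 3015, points: 9}
      - {gt: 3350, points: 10}
  satfat_g:
    max_points: 10
    steps:
      - {gt: 1, points: 1}
      - {gt: 2, points: 2}
      - {gt: 3, points: 3}
      - {gt: 4, points: 4}
      - {gt: 5, points: 5}
      - {gt: 6, points: 6}
      - {gt: 7, points: 7}
      - {gt: 8, points: 8}
      - {gt: 9, points: 9}
      - {gt: 10, points: 10}
    cat3_extension:
      max_points: 30
      steps:
        - {gt: 11.2, points: 11}
        - {gt: 12.5, points: 12}
        - {gt: 13.9, points: 13}
        - {gt: 15.5, points: 14}
        - {gt: 17.3, points: 15}
        - {gt: 19.3, points: 16}
        - {gt: 21.6, points: 17}
        - {gt: 24.1, points: 18}
        - {gt: 26.9, points: 19}
        - {gt: 30, points: 20}
        - {gt: 33.5, points: 21}
        - {gt: 37.4, points: 22}
        - {gt: 41.7, points: 23}
        - {gt: 46.6, points: 24}
        - {gt: 52, points: 25}
        - {gt: 58, points: 26}
        - {gt: 64.7, points: 27}
        - {gt: 72.3, points: 28}
        - {gt: 80.6, points: 29}
        - {gt: 90, points: 30}
  sugars_g:
    max_points: 10
    steps:
      - {gt: 5, points: 1}
      - {gt: 9, points: 2}
      - {gt: 13.5, points: 3}
      - {gt: 18, points: 4}
      - {gt: 22.5, points: 5}
      - {gt: 27, points: 6}
      - {gt: 31, points: 7}
      - {gt: 36, points: 8}
      - {gt: 40, points: 9}
      - {gt: 45, points: 10}
  sodium_mg:
    max_points: 10
    steps:
      - {gt: 90, points: 1}
      - {gt: 180, points: 2}
      - {gt: 270, points: 3}
      - {gt: 360, points: 4}
      - {gt: 450, points: 5}
      - {gt: 540, points: 6}
      - {gt: 630, points: 7}
      - {gt: 720, points: 8}
      - {gt: 810, points: 9}
      - {gt: 900, points: 10}
    cat3_extension:
      max_points: 30
      steps:
        - {gt: 1005, points: 11}
        - {gt: 1121, points: 12}
        - {gt: 1251, points: 13}
        - {gt: 1397, points: 14}
        - {gt: 1559, points: 15}
        - {gt: 1740, points: 16}
        - {gt: 1942, points: 17}
        - {gt: 2167, points: 18}
        - {gt: 2419, points: 19}
        - {gt: 2700, points: 20}
        - {gt: 3014, points: 21}
        - {gt: 3364, points: 22}
        - {gt: 3754, points: 23}
        - {gt: 4190, points: 24}
        - {gt: 4677, points: 25}
        - {gt: 5219, points: 26}
        - {gt: 5826, points: 27}
        - {gt: 6502, points: 28}
        - {gt: 7257, points: 29}
        - {gt: 8100, points: 30}

modifying_components:
  fvnl_pct:
    max_points: 8
    steps:
      - {gt: 25, points: 1}
      - {gt: 43, points: 2}
      - {gt: 52, points: 3}
      - {gt: 63, points: 4}
      - {gt: 67, points: 5}
      - {gt: 80, points: 6}
      - {gt: 90, points: 7}
      - {ge: 100, points: 8}
  protein_g:
    max_points: 5
    steps:
      - {gt: 1.6, points: 1}
      - {gt: 3.2, points: 2}
      - {gt: 4.8, points: 3}
      - {gt: 6.4, points: 4}
      - {gt: 8, points: 5}
  fibre_g:
    max_points: 5
    steps:
      - {gt: 0.9, points: 1}
      - {gt: 1.9, points: 2}
      - {gt: 2.8, points: 3}
      - {gt: 3.7, points: 4}
      - {gt: 4.7, points: 5}
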