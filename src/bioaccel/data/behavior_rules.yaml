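# Default scoring bands for the five-component health-behavior score.
# Reconstructed from the AHA "Life's Essential 8" scheme (diet, physical
# activity, tobacco/nicotine, sleep, BMI components); edit to match a local
# protocol.  All component scores live on a 0-100 scale.

# Diet: the 0-10 count of intake recommendations met is first converted to a
# cohort percentile, then banded.  Bands are closed on the left edge:
# [lo, hi) -> score, last band closed on both ends.
diet_percentile_bands:
  - [95, 101, 100]
  - [75, 95, 80]
  - [50, 75, 50]
  - [25, 50, 25]
  - [0, 25, 0]
# Fallback when the cohort is too small for stable percentiles (< min_cohort
# rows): score = 10 * count.
diet_min_cohort: 50

# Physical activity: weekly minutes of moderate-to-vigorous activity (MVPA).
activity_bands:
  - [150, .inf, 100]
  - [120, 150, 90]
  - [90, 120, 80]
  - [60, 90, 60]
  - [30, 60, 40]
  - [1, 30, 20]
  - [0, 1, 0]

# Tobacco/nicotine: status x quit-duration lattice; secondhand (household)
# smoke exposure subtracts 20 points, floored at 0.
tobacco_scores:
  never: 100
  former_quit_5y_plus: 75
  former_quit_1_5y: 50
  former_quit_lt_1y: 25
  current: 0
secondhand_penalty: 20

# Sleep: self-reported average hours per night.
sleep_bands:
  - [7, 9, 100]
  - [9, 10, 90]
  - [6, 7, 70]
  - [5, 6, 40]
  - [10, .inf, 40]
  - [4, 5, 20]
  - [0, 4, 0]

# BMI, kg/m^2.
bmi_bands:
  - [0, 25, 100]
  - [25, 30, 70]
  - [30, 35, 30]
  - [35, 40, 15]
  - [40, .inf, 0]
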