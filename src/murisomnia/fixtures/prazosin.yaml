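# Prazosin dose-response, 3.5-month-old animals.
# Intraperitoneal injection at 10:00 (light phase); the analysis window is
# the first 2 h after injection.  Per genotype x dose state-time targets
# plant the published treatment-window compositions, giving NREM contrasts
# of +14.6 points (NTg, 2 mg/kg vs vehicle) and +14.2 points (Tg, 5 mg/kg
# vs vehicle).  NREM and REM percentages are the published values; wake is
# the complement so each composition sums to 100 (the published wake
# entries leave rows summing to 99.7-104.2).
name: prazosin
scenario: prazosin
injection_time: "10:00"
window_h: 2
animal_cv: 0.10
groups:
  NTg:
    "0":
      n: 11
      state_fractions: {light: {W: 0.402, NR: 0.545, R: 0.053}}
      mean_bout_s: {light: {W: 55.0, NR: 70.3, R: 60.0}}
    "1":
      n: 8
      state_fractions: {light: {W: 0.325, NR: 0.648, R: 0.027}}
      mean_bout_s: {light: {W: 55.0, NR: 105.6, R: 60.0}}
    "2":
      n: 8
      state_fractions: {light: {W: 0.287, NR: 0.691, R: 0.022}}
      mean_bout_s: {light: {W: 55.0, NR: 127.9, R: 60.0}}
    "5":
      n: 8
      state_fractions: {light: {W: 0.287, NR: 0.707, R: 0.006}}
      mean_bout_s: {light: {W: 55.0, NR: 134.2, R: 60.0}}
  Tg:
    "0":
      n: 11
      state_fractions: {light: {W: 0.481, NR: 0.465, R: 0.054}}
      mean_bout_s: {light: {W: 55.0, NR: 50.6, R: 60.0}}
    "1":
      n: 9
      state_fractions: {light: {W: 0.521, NR: 0.436, R: 0.043}}
      mean_bout_s: {light: {W: 55.0, NR: 44.3, R: 60.0}}
    "2":
      n: 9
      state_fractions: {light: {W: 0.612, NR: 0.358, R: 0.030}}
      mean_bout_s: {light: {W: 55.0, NR: 31.5, R: 60.0}}
    "5":
      n: 6
      state_fractions: {light: {W: 0.356, NR: 0.607, R: 0.037}}
      mean_bout_s: {light: {W: 55.0, NR: 89.5, R: 60.0}}
planted:
  nrem_contrast_points:
    NTg_2_vs_vehicle: 14.6
    Tg_5_vs_vehicle: 14.2
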