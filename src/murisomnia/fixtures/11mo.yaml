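# Baseline cohort, 11-month-old animals (Tg - NTg: dark wake +15.8,
# dark NREM -14.5; light wake +10, light NREM -7 points; REM contrasts
# below the significance threshold at this age).
name: 11mo
scenario: baseline_cohort
start_time: "20:00"
duration_h: 24
animal_cv: 0.10
groups:
  NTg:
    n: 6
    state_fractions:
      dark:  {W: 0.550, NR: 0.386, R: 0.064}
      light: {W: 0.340, NR: 0.570, R: 0.090}
    mean_bout_s:
      dark:  {W: 182.7, NR: 108.3, R: 57.7}
      light: {W: 62.8, NR: 93.8, R: 68.2}
  Tg:
    n: 4
    state_fractions:
      dark:  {W: 0.708, NR: 0.241, R: 0.051}
      light: {W: 0.440, NR: 0.500, R: 0.060}
    mean_bout_s:
      dark:  {W: 428.0, NR: 117.3, R: 63.8}
      light: {W: 95.0, NR: 97.6, R: 61.3}
planted_contrasts:
  dark_wake_Tg_minus_NTg: 15.8
  dark_nrem_Tg_minus_NTg: -14.5
  light_wake_Tg_minus_NTg: 10.0
  light_nrem_Tg_minus_NTg: -7.0
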