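# Baseline cohort, 7-month-old animals (Tg - NTg: dark wake +20.3,
# dark NREM -17.7, dark REM -2.6; light wake +5.6, light NREM -5.7 points).
name: 7mo
scenario: baseline_cohort
start_time: "20:00"
duration_h: 24
animal_cv: 0.10
groups:
  NTg:
    n: 5
    state_fractions:
      dark:  {W: 0.550, NR: 0.386, R: 0.064}
      light: {W: 0.340, NR: 0.570, R: 0.090}
    mean_bout_s:
      dark:  {W: 160.2, NR: 98.0, R: 63.4}
      light: {W: 48.0, NR: 72.9, R: 61.4}
  Tg:
    n: 7
    state_fractions:
      dark:  {W: 0.753, NR: 0.209, R: 0.038}
      light: {W: 0.396, NR: 0.513, R: 0.091}
    mean_bout_s:
      dark:  {W: 382.7, NR: 94.2, R: 76.0}
      light: {W: 63.1, NR: 73.9, R: 68.0}
planted_contrasts:
  dark_wake_Tg_minus_NTg: 20.3
  dark_nrem_Tg_minus_NTg: -17.7
  dark_rem_Tg_minus_NTg: -2.6
  light_wake_Tg_minus_NTg: 5.6
  light_nrem_Tg_minus_NTg: -5.7
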