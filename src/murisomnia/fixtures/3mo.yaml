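# Baseline cohort, 3-month-old animals.
# State-time fractions plant the published percent-time contrasts
# (Tg - NTg: dark wake +25.4, dark NREM -23.0, dark REM -2.4 points;
# light wake +5.5, light NREM -6.2 points).  Mean bout durations follow the
# published episode durations where those are jointly feasible with the
# percent-time targets; the NREM bout means are adjusted to the nearest
# feasible value (see docs/methods.md).
name: 3mo
scenario: baseline_cohort
start_time: "20:00"
duration_h: 24
animal_cv: 0.10
groups:
  NTg:
    n: 7
    state_fractions:
      dark:  {W: 0.550, NR: 0.386, R: 0.064}
      light: {W: 0.340, NR: 0.570, R: 0.090}
    mean_bout_s:
      dark:  {W: 162.3, NR: 100.3, R: 69.9}
      light: {W: 52.6, NR: 80.5, R: 72.6}
  Tg:
    n: 8
    state_fractions:
      dark:  {W: 0.804, NR: 0.156, R: 0.040}
      light: {W: 0.395, NR: 0.508, R: 0.097}
    mean_bout_s:
      dark:  {W: 350.0, NR: 59.9, R: 65.0}
      light: {W: 91.3, NR: 100.9, R: 68.5}
    # waking spectrum shifted toward fast frequencies (beta / low gamma up,
    # delta down), the transgenic hyperarousal signature
    band_fractions:
      W:  {delta: 0.11, theta: 0.15, alpha: 0.09, beta: 0.18, low_gamma: 0.25}
      NR: {delta: 0.50, theta: 0.12, alpha: 0.07, beta: 0.05, low_gamma: 0.06}
      R:  {delta: 0.10, theta: 0.45, alpha: 0.10, beta: 0.08, low_gamma: 0.09}
planted_contrasts:
  dark_wake_Tg_minus_NTg: 25.4
  dark_nrem_Tg_minus_NTg: -23.0
  dark_rem_Tg_minus_NTg: -2.4
  light_wake_Tg_minus_NTg: 5.5
  light_nrem_Tg_minus_NTg: -6.2
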