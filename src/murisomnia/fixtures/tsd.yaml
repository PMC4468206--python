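# Total sleep deprivation and rebound, 3-month-old animals.
# 48-h record from 20:00: day-1 baseline, 6-h enforced wakefulness
# 08:00-14:00 on day 2, 2-h rebound 14:00-16:00, circadian-matched
# baseline window 14:00-16:00 on day 1.  Residual sleep inside the TSD
# window and the rebound shift in normalized NREM delta power are planted
# per group; the transgenic group additionally shows a rebound increase in
# NREM and REM time.
name: tsd
scenario: tsd
start_time: "20:00"
duration_h: 48
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
    residual_sleep: {NR: 0.0217, R: 0.0}
    rebound:
      delta_factor: 1.27
      # no significant duration rebound in controls
  Tg:
    n: 9
    state_fractions:
      dark:  {W: 0.804, NR: 0.156, R: 0.040}
      light: {W: 0.395, NR: 0.508, R: 0.097}
    mean_bout_s:
      dark:  {W: 350.0, NR: 59.9, R: 65.0}
      light: {W: 91.3, NR: 100.9, R: 68.5}
    residual_sleep: {NR: 0.0322, R: 0.0006}
    rebound:
      delta_factor: 1.18
      state_fractions: {W: 0.295, NR: 0.578, R: 0.127}
planted:
  tsd_wake_pct: {NTg: 97.83, Tg: 96.72}
  rebound_delta_shift_pct: {NTg: 27.0, Tg: 18.0}
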