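"""Total sleep deprivation and the homeostatic rebound.

Simulates the 48-h deprivation protocol (baseline day, 6-h enforced
wakefulness from light onset, 2-h rebound window) for both genotypes and
quantifies deprivation efficacy, the rebound shift in NREM delta power,
and the paired duration changes with a mixed genotype x period ANOVA.
"""

from murisomnia.pipeline import run_tsd

result = run_tsd("tsd", seed=1)

eff = result["efficacy"].groupby("group")["W"].mean()
print("wake during the 6-h deprivation window (planted NTg 97.83, Tg 96.72):")
print(eff.round(2).to_string())

shifts = result["delta_shifts"].groupby("group")["delta_shift_pct"].mean()
print("\nNREM delta power change, rebound vs baseline "
      "(planted NTg +27 %, Tg +18 %):")
print(shifts.round(1).to_string())

print("\nmixed ANOVA (genotype x period) on NREM percent time:")
for res in result["mixed_anova"]["NR"]:
    print(f"  {res.effect}: F({res.df_num},{res.df_den}) = {res.F:.2f}, "
          f"p = {res.p:.3f}")
print("-> deprivation was effective in both groups (>96 % wake); the delta "
      "rebound -- the homeostatic marker of sleep pressure -- is blunted in "
      "the transgenic group.")
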