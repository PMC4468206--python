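"""Dose-dependent NREM response to alpha-1 adrenergic blockade.

Simulates the prazosin treatment windows (2 h after a 10:00 injection) for
both genotypes at vehicle, 1, 2 and 5 mg/kg, and quantifies the NREM
percent-time change relative to vehicle with the two-way genotype x dose
ANOVA used for each comparison.
"""

from murisomnia.pipeline import run_prazosin

result = run_prazosin("prazosin", seed=1)

print("NREM change vs vehicle (percentage points):")
for dose, diff in sorted(result["nrem_contrasts"].items()):
    entries = ", ".join(f"{g}: {v:+.1f}" for g, v in diff.items())
    print(f"  {dose:g} mg/kg -> {entries}")

print("\ntwo-way ANOVA, 2 mg/kg vs vehicle:")
for res in result["anovas"][2.0]:
    print(f"  {res.effect}: F({res.df_num},{res.df_den}) = {res.F:.2f}, "
          f"p = {res.p:.4f}")
print("-> controls respond already at 2 mg/kg (planted +14.6 points) while "
      "transgenics need 5 mg/kg (planted +14.2 points): reduced sensitivity "
      "to noradrenergic blockade.")
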