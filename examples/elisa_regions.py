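"""Region-wise amyloid-beta-42 quantification.

Simulates a 3-month ELISA table (7 samples per brain region), normalizes
raw pg/ml readings to total protein (mg/ml), compares regions with a
one-way within-subject ANOVA plus Tukey follow-up, and prints the fold
excess of the prefrontal cortex over the subcortical regions.
"""

from murisomnia.pipeline import run_elisa

result = run_elisa("elisa", seed=1, age="3mo")

means = result["table"].groupby("region")["normalized_pg_mg"].mean()
print("normalized amyloid-beta-42 (pg/mg protein), group means:")
print(means.round(1).to_string())

print("\nfold ratios vs prefrontal cortex (planted 76 / 148 / 186):")
for region in ("thalamus", "brainstem", "hypothalamus"):
    fold = result["folds"][("prefrontal_cortex", region)]
    print(f"  prefrontal_cortex / {region}: {fold:.0f}-fold")

a = result["anova"]
print(f"\nwithin-subject ANOVA across regions: F({a.df_num},{a.df_den}) = "
      f"{a.F:.1f}, p = {a.p:.2g}")
print("-> cortical amyloid far exceeds the subcortical sleep-regulatory "
      "regions at this early age; the ANOVA confirms the region effect.")
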