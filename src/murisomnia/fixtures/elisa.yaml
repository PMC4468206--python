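# Region-wise amyloid-beta-42 ELISA scenarios.
# Only fold ratios between region means are published; absolute pg/mg
# levels are scenario parameters chosen so the 3-month prefrontal cortex
# exceeds the thalamus, brainstem and hypothalamus by the published 76-,
# 148- and 186-fold.  Later ages reproduce the qualitative progression
# (thalamus reaches the 3-month cortical order of magnitude by 7 months;
# hypothalamus and brainstem by 11 months) and are synthetic beyond that.
name: elisa
scenario: elisa
protein_mg_ml: 3.0
cv: 0.2
ages:
  3mo:
    n: 7
    region_means_pg_mg:
      prefrontal_cortex: 7600.0
      thalamus: 100.0
      brainstem: 51.351
      hypothalamus: 40.860
  7mo:
    n: 9
    region_means_pg_mg:
      prefrontal_cortex: 38000.0
      thalamus: 7600.0
      brainstem: 1800.0
      hypothalamus: 1500.0
  11mo:
    n: 7
    region_means_pg_mg:
      prefrontal_cortex: 76000.0
      thalamus: 15000.0
      brainstem: 7000.0
      hypothalamus: 7600.0
planted:
  fold_3mo:
    prefrontal_cortex_over_thalamus: 76.0
    prefrontal_cortex_over_brainstem: 148.0
    prefrontal_cortex_over_hypothalamus: 186.0
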