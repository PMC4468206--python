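# murisomnia

Murine polysomnography analysis: vigilance-state scoring, EEG spectral
band analysis, sleep-architecture metrics, sleep-deprivation and
pharmacological protocol analyses, ELISA normalization, and the matching
ANOVA battery — all driven by a semi-Markov EEG/EMG simulator that plants
known effect magnitudes so every stage is verifiable end to end.

## The problem

Rodent sleep studies score continuous two-channel recordings (cortical EEG
plus nuchal EMG, 512 Hz) into wake (W), NREM sleep (NR) and REM sleep (R)
on a 5-s epoch grid, then quantify how an intervention — a transgene, six
hours of enforced wakefulness, a drug — reshapes sleep. The quantities of
interest are percent time per state per light/dark phase, bout (episode)
durations and state-transition counts, normalized EEG band power (delta
0.5–4.5 Hz, theta 6–10 Hz, alpha 10–14 Hz, beta 14–20 Hz, low gamma
20–50 Hz), the homeostatic rebound in NREM delta power after sleep
deprivation, treatment-window state composition, and region-wise
amyloid-β42 levels normalized to total protein. This package implements
that entire workflow for researchers who need a tested, scriptable
alternative to manual scoring and spreadsheet statistics — and, because
raw recordings from such studies are rarely shared, ships a synthetic
backbone that reproduces the statistical structure of a real study.

## The models at the core

**Simulator.** Vigilance states follow a semi-Markov chain on the epoch
grid: bout lengths are geometric with phase-specific means m_s (so the
per-epoch hazard of leaving state s is 1/m_s), and transitions follow an
embedded kernel in which REM is reachable only from NREM
(W→NR; NR→W or R; R→W or NR). Given target occupancies f_s and bout means
m_s, the kernel's two free probabilities solve in closed form from the
embedded stationary weights ν_s ∝ f_s/m_s, so planted percent-time targets
are exact stationary properties of the simulated chain. Per-epoch EEG is
described by state-conditional band-fraction templates (epoch fidelity) or
rendered as band-limited Gaussian noise mixtures with state-dependent EMG
tone and phasic bursts (signal fidelity). Between-animal variability is
multiplicative lognormal noise on the state-time targets (CV 0.10).

**Scorer.** Per 1-s subwindow features (EEG/EMG RMS, delta fraction,
theta/delta ratio from a short periodogram) feed threshold rules —
EMG-active ⇒ W; quiet EMG with delta-dominant or high-amplitude EEG ⇒ NR;
theta-dominant EEG with atonia ⇒ R — and each 5-s epoch takes the label
holding >50 % of its subwindows. Thresholds are calibrated per recording
from the feature distributions (Otsu cluster splits with cross-feature
consensus checks), since absolute microvolt levels vary with electrode
placement.

**Statistics.** Two-way between-subject ANOVA (Type-III sums of squares),
mixed (split-plot) ANOVA, one-way repeated-measures ANOVA, Tukey's
studentized-range and Bonferroni follow-ups, simple-effects analysis, and
the pooled-variance unpaired t-test, implemented from first-principles
sums of squares and cross-checked against independent references in the
test suite.

## Worked example

```sh
python examples/sleep_architecture.py
```

simulates the packaged 3-month baseline cohort (7 control, 8 transgenic
animals, 24 h each at epoch fidelity) and prints:

```
percent time per state (group mean +/- SEM):
                    mean   sem  n
group phase state
NTg   dark  NR     42.38  1.77  7
            R       5.61  0.48  7
            W      52.01  1.97  7
...
Tg - NTg contrasts (percentage points), recovered vs planted:
  dark  W : recovered +26.81, planted  +25.4
  dark  NR: recovered -25.53, planted  -23.0
  light W : recovered  +3.33, planted   +5.5
```

The contrasts are the genotype effects the fixture plants (transgenic
hyperarousal: more wake, less NREM); a single simulated cohort recovers
them to within sampling error, and averaging over ten cohorts tightens the
recovery to fractions of a percentage point. The other scripts in
`examples/` walk through scoring raw signal, spectral band analysis, the
deprivation/rebound protocol, the prazosin dose response and the ELISA
region comparison. A thin CLI mirrors the library
(`murisomnia run --config 3mo --out out/ --seed 1`, plus `simulate`,
`score`, `spectra`, `architecture`, `tsd`, `treatment`, `elisa`, `stats`,
`report`).

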