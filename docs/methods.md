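# Methods

This note documents the models, parameter choices and numerical
conventions behind the package, and what its synthetic validation does and
does not establish.

## Vigilance-state model

States W (wake), NR (NREM sleep), R (REM sleep) evolve on a fixed 5-s
epoch grid. Bout (episode) durations are geometric at epoch resolution
with phase-specific means — the simplest memoryless dwell model consistent
with reporting only mean episode durations; heavier-tailed dwell
distributions are out of scope. The embedded transition kernel imposes the
standard rodent constraint that REM is entered only from NREM: W→NR
always, NR→W with probability a (else R), R→W with probability b (else
NR). Explicit kernels (including absorbing states) can be supplied for
degenerate scenarios.

Because geometric dwells are memoryless, the chain is simulated bout-wise
and a light/dark boundary simply redraws the remaining dwell under the new
phase's mean — every epoch therefore evolves under exactly its own phase's
parameters, and the chain initialized from the target occupancies is
stationary, so planted percent-time targets are exact expectations at any
record length.

### Solving the kernel from planted targets

Given target occupancies f = (f_W, f_NR, f_R) and mean bouts m (in
epochs), the embedded stationary weights are ν_s ∝ f_s/m_s and the kernel
probabilities solve as a = 1 − ν_R/ν_NR, b = (ν_W − ν_NR + ν_R)/ν_R. A
solution exists iff f_NR/m_NR lies between f_W/m_W and f_W/m_W + f_R/m_R
(every NREM bout must be entered from a wake or REM exit). The packaged
fixtures are authored inside this window. When per-animal variability
pushes a draw outside it, the animal's NREM bout mean is recentered to the
window midpoint — occupancy targets (the planted, analyzed quantities)
stay exactly attainable while bout length absorbs the variability.
Projecting the kernel instead was tried and rejected: it biased NREM
occupancy by up to 3 percentage points in compositions with very little
REM.

### Fixture parameterization

Published studies of this design report group *contrasts* (e.g. transgenic
minus control percent wake) rather than absolute occupancies, and report
bout durations and transition counts in tables that are not exactly
consistent with a single stationary chain (duration × count can exceed the
phase length). The fixtures therefore (a) fix control absolute occupancies
at typical C57BL/6-background values (dark phase W/NR/R = 55.0/38.6/6.4 %,
light 34.0/57.0/9.0 %), (b) derive the transgenic occupancies by adding
the published contrasts exactly — these are the acceptance-tested planted
quantities — and (c) keep published bout durations where they are jointly
feasible with the occupancies (e.g. control light-phase wake bouts of
52.6 s), adjusting the remaining NREM bout means to the feasible window's
midpoint. One published treatment-window composition summed to 104.2 %;
its NREM and REM values were kept and wake set to the complement.

Between-animal variability multiplies each animal's per-phase state-time
targets by independent lognormal factors with unit mean and CV 0.10
(group-level dispersion consistent with the published SEMs; animal-level
variance is not identifiable from group summaries, a stated limitation).
Per-animal seeds derive from the cohort master seed via
`numpy.random.SeedSequence.spawn`, so any animal is reproducible in
isolation.

## Synthetic EEG/EMG

Epoch fidelity emits per-epoch canonical band fractions (delta, theta,
alpha, beta, low gamma, fractions of total 0.125–100 Hz power) directly
from state templates times lognormal jitter (CV 0.05 per band,
renormalized), bypassing signal synthesis so cohort-scale experiments run
in seconds. Signal fidelity renders 512-Hz EEG as a sum of band-limited
Gaussian noise components scaled per epoch so each band's share of
variance matches the state template and the epoch RMS matches the state
amplitude (defaults: wake 40 µV, NREM 90 µV, REM 45 µV); the EMG is
band-limited noise at state-dependent tonic RMS (25/8/2 µV) with
Poisson-timed 0.2-s multiplicative bursts in wake (8/min, gain 4).

Templates: NREM delta fraction 0.50; REM theta 0.45 with delta 0.10; wake
roughly flat with elevated beta (0.14) and low gamma (0.20). The
transgenic waking template shifts further toward fast frequencies (delta
0.11, beta 0.18, low gamma 0.25). Rebound windows scale the NREM delta
fraction by a planted factor (1.27 control, 1.18 transgenic), rescaling
the other bands so fractions remain normalized — the planted normalized
delta change is therefore exact.

What the generator does **not** emulate: circadian drift beyond the
square-wave light/dark parameter switch (no Process-S/Process-C
dynamics), artifacts (the emulated recordings are artifact-free by
construction), 1/f spectral background, state-transition ambiguity at
sub-epoch resolution, and electrode-placement covariance between
amplitude and spectrum. Scorer-recovery results on this synthetic data
therefore demonstrate internal consistency of the pipeline, not
equivalence to a human scorer on real recordings.

## Scoring

Signals are zero-phase band-passed channel-wise (EEG 0.5–80 Hz, EMG
20–40 Hz, 4th-order Butterworth applied forward and backward). Features
are computed on 1-s subwindows — the finest grid on which the
majority-of-epoch rule and sub-5-s microarousal detection are both well
defined: EEG and EMG RMS, and delta fraction, theta fraction and
theta/delta ratio from a 1-s Hann periodogram (distinct from the
reporting-grade 4096-point FFT). Rules: EMG RMS ≥ emg_wake ⇒ W; else
delta ≥ delta_high or EEG RMS ≥ eeg_amp_high (the high-amplitude
slow-wave signature, the lower-variance of the two NREM cues) ⇒ NR; else
theta/delta ≥ 2 with EMG ≤ emg_atonia ⇒ R; else W. Epochs take the label
with ≥3 of 5 subwindows; 2/2/1 ties break to the previous epoch's state if
tied, else wake (continuity is the least surprising rule; the >50 %
criterion itself leaves ties undefined).

Calibration is per recording: thresholds come from Otsu cluster splits of
the subwindow feature distributions rather than fixed microvolt cutoffs
(amplitude varies with electrode placement) and rather than fixed
percentiles (a percentile lands inside a state's cluster whenever that
state's prevalence crosses it). Candidate splits are validated before
use: the high-delta and high-EEG-amplitude subwindow sets must coincide
(Jaccard ≥ 0.6) to establish an NREM cluster — spurious splits of
unimodal noise overlap near chance — and the EMG wake threshold must stay
quiet in ≥90 % of EEG-identified sleep. On single-state recordings these
checks fail closed: delta dominance falls back to a fixed 0.35 cutoff and
EMG-based wake is disabled, leaving classification to the EEG rules.
Microarousals are maximal wake runs of 1–4 subwindows flanked by sleep;
they are reported as events and never alter epoch labels.

## Spectral analysis

Reporting-grade spectra: each 2560-sample epoch is Hanning-windowed,
zero-padded to 4096 points and squared-magnitude transformed, giving a
0.125-Hz grid (512/4096); bins 1–800 cover 0.125–100 Hz. (A 0.2-Hz
"frequency resolution" is sometimes quoted alongside these parameters;
the two cannot both be exact at 512 Hz with a 4096-point FFT, and
0.125 Hz is taken as authoritative.) The Hanning coherent-gain correction
is applied — a constant that cancels under normalization but keeps
un-normalized power on a consistent scale. Normalization divides by the
800-bin sum, removing between-animal amplitude differences from electrode
placement. Band edges are half-open [low, high) so adjacent bands never
share a bin; a band's first bin is the first bin ≥ its lower edge. Both
the 6–10 Hz theta and the 7–10 Hz REM-theta variants are provided as
named bands. State×phase spectra are means of per-epoch normalized
spectra (unit sum is preserved exactly). Welch/multitaper estimation and
time-frequency analysis are out of scope.

## Architecture, protocols, windows

An episode is a maximal run of equal epochs; a transition is an epoch
whose predecessor differs (the record's first epoch never counts), making
transition counts differ from episode counts by at most the boundary
episode. Episodes spanning the light/dark boundary belong to the phase of
their first epoch and are not split (boundary effect ≤ 1 episode per
phase). No minimum episode duration is imposed — a single 5-s epoch is a
valid bout, consistent with microarousal-permissive scoring. Phases:
light = 08:00–20:00 by epoch start time.

The deprivation design places 6 h of enforced wakefulness at light onset
of the post-baseline day, the rebound window in the 2 h immediately after,
and the baseline window at the same clock time (14:00–16:00) of the
baseline day — clock-matching removes the circadian confound; the choice
of baseline window is this package's convention, documented rather than
asserted as universal. Deprivation efficacy is flagged below 96 % wake
(configurable; the level gentle handling achieves in practice). Residual
sleep inside the window is drawn binomially per epoch and placed as brief
intrusions, REM only adjacent to NREM. The rebound delta shift is
100·(delta_rebound − delta_baseline)/delta_baseline on window-averaged
normalized NREM spectra. Treatment windows are the 2 h from injection
(10:00); dose contrasts are group-mean differences against vehicle. ELISA
normalization divides pg/ml readings by per-sample protein (mg/ml); fold
ratios are ratios of group means (matching "-fold greater" phrasing), not
means of per-sample ratios, which makes them exactly transitive on
noiseless tables.

## Statistics

Implemented from first-principles sums of squares. Unbalanced
between-subject designs use Type-III (sum-to-zero coding, each effect
tested after all others) — the convention matching "main effect" language
under imbalance; the choice matters only for unbalanced cells and is
verified against an independent reference implementation on random
designs. The mixed ANOVA tests the between factor against
subjects-within-groups and the within factor and interaction against the
within-subject residual; sphericity corrections are omitted because the
designs used here have two-level within factors (for >2 levels they would
be needed). Tukey follow-ups use the Tukey–Kramer studentized-range
statistic with the omnibus error term; simple effects test one factor at
each level of the other against the omnibus error. The t-test is
pooled-variance with the convention p = 1 for two zero-variance samples
with equal means. Significance is conventionally 0.05. Null calibration
(type-I error within [0.03, 0.07] at 1000 replicates) is part of the test
suite.

## Problem sizes and tolerances

Validation experiments use desk-scale sizes chosen to put Monte-Carlo
error well inside each tolerance: baseline cohorts of 15 animals × 24 h at
epoch fidelity, 10 replicate cohorts (contrast tolerance ±2 percentage
points; observed seed-to-seed SD ≈ 2.5 points, so the 10-seed mean has
SEM ≈ 0.8); deprivation runs of 16 animals × 48 h, 10 seeds (window
composition ±0.5 points; delta shift ±3 points); treatment windows of
2 h × 69 animals, 10 seeds (±2 points); ELISA tables of 7 samples ×
4 regions, 20 seeds (fold ratio ±15 %). Scorer validation uses ten 1-h
signal-fidelity records (agreement ≥90 %; observed ≈99 %). The
acceptance script runs all of these in well under a minute on one CPU.

## Known limitations

Geometric bouts underrepresent the long-bout tail of real wake episodes;
the published long dark-phase wake durations for transgenics are not
jointly attainable with the published occupancies in any two-parameter
kernel of this shape, so the fixtures prioritize occupancies (the
acceptance quantities). Animal-level variance is an assumption, not an
inference. The scorer's thresholds operationalize visual criteria; no
claim of equivalence to any particular human scorer is made. The
rem_entry_rule=False kernel variant matches occupancies only
approximately and exists for ablation, not production use.
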