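"""Synthetic polysomnography with planted, recoverable effects.

The generator emulates murine sleep at two fidelities:

* ``epoch`` fidelity draws a vigilance-state trajectory from a semi-Markov
  model -- geometric bout lengths at 5-s epoch resolution with
  phase-specific means, and a transition kernel in which REM is reachable
  only from NREM (W <-> NR, NR -> R, R -> {W, NR}) -- and, when spectra are
  needed, emits per-epoch normalized band fractions directly from
  state-specific templates.  This is the fast path used for cohort-scale
  experiments.
* ``signal`` fidelity additionally renders raw 512-Hz EEG/EMG: the EEG is a
  sum of band-limited Gaussian noise components weighted by the state's
  band template (delta-dominant NREM, theta-peaked REM, low-amplitude
  broadband wake), the EMG has state-dependent tone (phasic bursts in wake,
  reduced tone in NREM, atonia in REM).  This path exists to validate the
  scorer against known truth.

Percent-time targets and mean bout durations jointly determine the
transition kernel: with embedded stationary weights nu_s proportional to
(target fraction / mean bout), the two free kernel probabilities solve
exactly when the targets are mutually consistent, and are otherwise
projected onto the feasible set by bounded least squares on the occupancy
error.  Between-animal variability multiplies each animal's state-time
targets by independent lognormal factors (unit mean, configurable CV).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize

from .io import LIGHT_ONSET, Hypnogram, Recording, STATES

PHASES = ("light", "dark")
_BAND_NAMES = ("delta", "theta", "alpha", "beta", "low_gamma")

#: State-conditional EEG band-fraction templates (fractions of total
#: 0.125-100 Hz power; the remainder sits in the 4.5-6 and >50 Hz gaps).
DEFAULT_BAND_FRACTIONS: dict[str, dict[str, float]] = {
    "W": {"delta": 0.15, "theta": 0.16, "alpha": 0.10, "beta": 0.14, "low_gamma": 0.20},
    "NR": {"delta": 0.50, "theta": 0.12, "alpha": 0.07, "beta": 0.05, "low_gamma": 0.06},
    "R": {"delta": 0.10, "theta": 0.45, "alpha": 0.10, "beta": 0.08, "low_gamma": 0.09},
}

#: EEG RMS amplitude per state, µV (NREM is high-amplitude slow activity).
DEFAULT_EEG_AMPLITUDE = {"W": 40.0, "NR": 90.0, "R": 45.0}

#: EMG per state: (tonic RMS µV, phasic burst rate per minute, burst gain).
DEFAULT_EMG_LEVEL = {"W": (25.0, 8.0, 4.0), "NR": (8.0, 0.0, 0.0), "R": (2.0, 0.0, 0.0)}


@dataclass
class GeneratorConfig:
    """Parameterization of one simulated animal group.

    ``state_fractions`` and ``mean_bout_s`` are maps phase -> state ->
    value; a config may carry a single phase when only that phase will be
    simulated (e.g. a 2-h post-injection window in the light phase).
    """

    group_label: str
    state_fractions: dict[str, dict[str, float]]
    mean_bout_s: dict[str, dict[str, float]]
    band_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_BAND_FRACTIONS.items()}
    )
    eeg_amplitude: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EEG_AMPLITUDE))
    emg_level: dict[str, tuple] = field(default_factory=lambda: dict(DEFAULT_EMG_LEVEL))
    transition_kernel: dict[str, dict[str, float]] | None = None
    effect_overrides: dict = field(default_factory=dict)
    rem_entry_rule: bool = True
    fidelity: str = "epoch"
    sampling_rate: float = 512.0
    epoch_s: float = 5.0
    light_onset: dt.time = LIGHT_ONSET
    animal_cv: float = 0.10
    band_jitter_cv: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fidelity not in ("epoch", "signal"):
            raise ValueError(f"unknown fidelity {self.fidelity!r}")
        if self.epoch_s <= 0 or self.sampling_rate <= 0:
            raise ValueError("epoch_s and sampling_rate must be positive")
        for phase, bouts in self.mean_bout_s.items():
            for state, m in bouts.items():
                if m <= self.epoch_s:
                    raise ValueError(
                        f"mean bout for {state}/{phase} must exceed one epoch "
                        f"({m} s <= {self.epoch_s} s)"
                    )
        for phase, fr in self.state_fractions.items():
            total = sum(fr.get(s, 0.0) for s in STATES)
            if not np.isfinite(total) or total <= 0:
                raise ValueError(f"state fractions for {phase} must sum to a positive value")
        for state, bands in self.band_fractions.items():
            total = sum(bands.values())
            if not np.isfinite(total) or total <= 0 or min(bands.values()) < 0:
                raise ValueError(f"band weights for {state} must be nonnegative with positive sum")
            if total > 1 + 1e-9:
                raise ValueError(f"band fractions for {state} exceed 1")

    def with_override(self, name: str) -> "GeneratorConfig":
        """Return a copy with the named effect override merged in.

        Overrides are shallow per top-level field, deep for the nested
        phase/state maps (``state_fractions``, ``mean_bout_s``,
        ``band_fractions``).
        """
        try:
            delta = self.effect_overrides[name]
        except KeyError as exc:
            raise KeyError(f"no effect override named {name!r}") from exc
        changes: dict = {}
        for key, value in delta.items():
            if key in ("state_fractions", "mean_bout_s", "band_fractions"):
                merged = {k: dict(v) for k, v in getattr(self, key).items()}
                for outer, inner in value.items():
                    merged.setdefault(outer, {}).update(inner)
                changes[key] = merged
            else:
                changes[key] = value
        return replace(self, **changes)


@dataclass
class PlantedTruth:
    """Ground truth exported with each simulated animal."""

    true_hypnogram: Hypnogram
    true_band_fractions: pd.DataFrame | None = None
    group_effects: dict = field(default_factory=dict)
    target_fractions: dict = field(default_factory=dict)


@dataclass
class AnimalData:
    subject_id: str
    group: str
    hypnogram: Hypnogram
    truth: PlantedTruth
    recording: Recording | None = None
    band_fractions: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Transition-kernel derivation
# ---------------------------------------------------------------------------

def derive_kernel(fractions: np.ndarray, mean_epochs: np.ndarray) -> tuple[float, float, bool]:
    """Solve the two free kernel probabilities from occupancy targets.

    States ordered (W, NR, R).  The embedded chain is W->NR (always),
    NR->W with probability ``a`` else R, R->W with probability ``b`` else
    NR.  Returns (a, b, exact); when the exact solution leaves [0, 1]^2 it
    is replaced by the bounded least-squares projection minimizing the
    squared occupancy error.
    """
    f = np.asarray(fractions, dtype=float)
    f = f / f.sum()
    m = np.asarray(mean_epochs, dtype=float)
    nu = f / m
    nu = nu / nu.sum()
    eps = 1e-12
    a = 1.0 - nu[2] / max(nu[1], eps)
    b = (nu[0] - nu[1] + nu[2]) / max(nu[2], eps)
    if -1e-9 <= a <= 1 + 1e-9 and -1e-9 <= b <= 1 + 1e-9:
        return float(np.clip(a, 0, 1)), float(np.clip(b, 0, 1)), True

    def occupancy(x: np.ndarray) -> np.ndarray:
        aa, bb = x
        nu_x = np.array([aa + bb * (1 - aa), 1.0, 1 - aa])
        occ = nu_x * m
        return occ / occ.sum()

    res = minimize(
        lambda x: float(((occupancy(x) - f) ** 2).sum()),
        x0=[float(np.clip(a, 0, 1)), float(np.clip(b, 0, 1))],
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        method="L-BFGS-B",
    )
    return float(res.x[0]), float(res.x[1]), False


def center_nrem_bout(fractions: np.ndarray, mean_epochs: np.ndarray) -> np.ndarray:
    """Return bout means with the NREM dwell recentered for exact solvability.

    The kernel solves exactly iff f_NR/m_NR lies between f_W/m_W and
    f_W/m_W + f_R/m_R.  Placing it mid-window by adjusting the NREM bout
    mean keeps the occupancy targets exactly attainable; wake and REM bout
    means stay as configured.  Used per animal when between-animal jitter
    pushes the configured combination outside the feasible window.
    """
    f = np.asarray(fractions, dtype=float)
    m = np.asarray(mean_epochs, dtype=float).copy()
    denom = f[0] / m[0] + 0.5 * f[2] / m[2]
    if f[1] > 0 and denom > 0:
        m[1] = max(f[1] / denom, 1.0 + 1e-9)
    return m


def _kernel_matrix(config: GeneratorConfig, fractions: np.ndarray,
                   mean_epochs: np.ndarray) -> np.ndarray:
    """Embedded transition matrix honoring the REM-entry rule."""
    if config.transition_kernel is not None:
        K = np.zeros((3, 3))
        for i, src in enumerate(STATES):
            row = config.transition_kernel.get(src, {})
            for j, dst in enumerate(STATES):
                K[i, j] = row.get(dst, 0.0)
            total = K[i].sum()
            if total <= 0:
                # unreachable-state row left unspecified: exit uniformly
                K[i] = [0.0 if j == i else 0.5 for j in range(3)]
                total = 1.0
            K[i] /= total
        if config.rem_entry_rule and K[0, 2] > 0:
            raise ValueError("rem_entry_rule forbids W -> R transitions")
        return K
    if config.rem_entry_rule:
        a, b, _ = derive_kernel(fractions, mean_epochs)
        return np.array([[0.0, 1.0, 0.0], [a, 0.0, 1 - a], [b, 1 - b, 0.0]])
    # unconstrained variant: route exits toward the embedded stationary
    # weights of the destinations (occupancy matched approximately)
    nu = fractions / mean_epochs
    K = np.zeros((3, 3))
    for i in range(3):
        w = nu.copy()
        w[i] = 0.0
        K[i] = w / w.sum()
    return K


def _phase_codes(start_time: dt.datetime, n_epochs: int, epoch_s: float,
                 light_onset: dt.time) -> np.ndarray:
    """0 for light, 1 for dark, per epoch start time."""
    on = light_onset.hour * 3600 + light_onset.minute * 60 + light_onset.second
    off = (on + 12 * 3600) % 86400
    sec0 = start_time.hour * 3600 + start_time.minute * 60 + start_time.second
    secs = (sec0 + epoch_s * np.arange(n_epochs)) % 86400
    light = (secs >= on) & (secs < off) if on < off else (secs >= on) | (secs < off)
    return np.where(light, 0, 1).astype(np.int8)


def _phase_params(config: GeneratorConfig, phase: str,
                  fractions_override: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    fr_map = (fractions_override or config.state_fractions)[phase]
    bouts = config.mean_bout_s[phase]
    f = np.array([fr_map.get(s, 0.0) for s in STATES], dtype=float)
    m = np.array([bouts[s] for s in STATES], dtype=float) / config.epoch_s
    return f / f.sum(), m


def _simulate_states(
    config: GeneratorConfig,
    n_epochs: int,
    phase_codes: np.ndarray,
    rng: np.random.Generator,
    fractions_override: dict | None = None,
    initial_state: int | None = None,
) -> np.ndarray:
    """Core bout-level simulation on the epoch grid.

    Dwell times are geometric (memoryless), so at a light/dark boundary the
    remaining dwell is simply redrawn under the new phase's mean -- each
    epoch therefore evolves under exactly the parameters of its own phase.
    """
    params = {}
    for code, phase in ((0, "light"), (1, "dark")):
        if (phase_codes == code).any():
            f, m = _phase_params(config, phase, fractions_override)
            if config.transition_kernel is None and config.rem_entry_rule:
                _, _, exact = derive_kernel(f, m)
                if not exact:
                    m = center_nrem_bout(f, m)
            K = _kernel_matrix(config, f, m)
            params[code] = (f, m, K.cumsum(axis=1))
    states = np.empty(n_epochs, dtype=np.int8)
    boundaries = np.flatnonzero(phase_codes[1:] != phase_codes[:-1]) + 1
    ph0 = int(phase_codes[0])
    f0 = params[ph0][0]
    if initial_state is None:
        s = int(np.searchsorted(f0.cumsum(), rng.random(), side="right"))
        s = min(s, 2)
    else:
        s = initial_state
    t = 0
    while t < n_epochs:
        ph = int(phase_codes[t])
        f, m, Kcum = params[ph]
        j = int(np.searchsorted(boundaries, t, side="right"))
        nb = int(boundaries[j]) if j < boundaries.size else n_epochs
        d = int(rng.geometric(1.0 / m[s]))
        end = min(t + d, nb, n_epochs)
        states[t:end] = s
        if t + d <= nb and end < n_epochs:
            u = rng.random()
            s = int(np.searchsorted(Kcum[s], u, side="right"))
            s = min(s, 2)
        t = end
    return states


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_hypnogram(
    config: GeneratorConfig,
    duration_s: float,
    start_time: dt.datetime,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "",
    fractions_override: dict | None = None,
) -> Hypnogram:
    """Draw a semi-Markov vigilance-state trajectory.

    ``duration_s`` must be a whole number of epochs.  Deterministic under a
    fixed integer seed.
    """
    n_epochs, rem = divmod(duration_s, config.epoch_s)
    if rem:
        raise ValueError(
            f"duration {duration_s} s is not a multiple of the {config.epoch_s}-s epoch"
        )
    n_epochs = int(n_epochs)
    if n_epochs == 0:
        raise ValueError("duration must cover at least one epoch")
    rng = _as_rng(seed)
    phase_codes = _phase_codes(start_time, n_epochs, config.epoch_s, config.light_onset)
    states = _simulate_states(config, n_epochs, phase_codes, rng, fractions_override)
    return Hypnogram(
        states=np.array(STATES, dtype="U2")[states],
        start_time=start_time,
        epoch_s=config.epoch_s,
        subject_id=subject_id or config.group_label,
    )


# ---------------------------------------------------------------------------
# Epoch-fidelity spectra
# ---------------------------------------------------------------------------

def boost_delta(template: dict[str, float], factor: float) -> dict[str, float]:
    """Scale a band template's delta fraction by ``factor``.

    Non-delta bands (and the implicit out-of-band remainder) are rescaled
    so the template still describes fractions of total power; the planted
    normalized delta fraction is therefore exactly ``delta * factor``.
    """
    d = template["delta"]
    d_new = d * factor
    if not 0 <= d_new < 1:
        raise ValueError("boosted delta fraction must stay below 1")
    scale = (1 - d_new) / (1 - d)
    out = {k: v * scale for k, v in template.items()}
    out["delta"] = d_new
    return out


def generate_band_fractions(
    hypnogram: Hypnogram,
    config: GeneratorConfig,
    seed: int | np.random.Generator | None = None,
    delta_factor: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-epoch normalized EEG band fractions (epoch-fidelity path).

    Each epoch receives its state's template, optionally with a per-epoch
    delta boost (``delta_factor``, e.g. a rebound window), multiplied by
    independent lognormal jitter per band and renormalized.
    """
    rng = _as_rng(seed)
    n = len(hypnogram)
    cols = list(_BAND_NAMES) + ["rest"]
    base = np.empty((n, 6))
    templates = {}
    for s in STATES:
        t = config.band_fractions[s]
        templates[s] = np.array([t[b] for b in _BAND_NAMES] + [1 - sum(t.values())])
    for i, s in enumerate(STATES):
        base[hypnogram.states == s] = templates[s]
    if delta_factor is not None:
        factor = np.asarray(delta_factor, dtype=float)
        d = base[:, 0]
        d_new = d * factor
        scale = (1 - d_new) / (1 - d)
        base = base * scale[:, None]
        base[:, 0] = d_new
    cv = config.band_jitter_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        base = base * rng.lognormal(-(sigma**2) / 2, sigma, size=base.shape)
    base /= base.sum(axis=1, keepdims=True)
    return pd.DataFrame(base, columns=cols)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

_SYNTH_BANDS = {
    "delta": (0.5, 4.5),
    "theta": (6.0, 10.0),
    "alpha": (10.0, 14.0),
    "beta": (14.0, 20.0),
    "low_gamma": (20.0, 50.0),
}
_GAP_BANDS = {"gap_mid": (4.5, 6.0), "gap_high": (50.0, 80.0)}
_BURST_S = 0.2


def _band_noise(n: int, band: tuple[float, float], fs: float,
                rng: np.random.Generator) -> np.ndarray:
    from scipy import signal as sps

    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, white)
    rms = np.sqrt((x**2).mean())
    return x / max(rms, 1e-12)


def synthesize_signals(
    hypnogram: Hypnogram,
    config: GeneratorConfig,
    seed: int | np.random.Generator | None = None,
) -> Recording:
    """Render raw EEG/EMG for a hypnogram (signal fidelity only).

    EEG: per-band unit-RMS Gaussian noise scaled per epoch so the band's
    share of power matches the state template and the epoch RMS matches the
    state amplitude.  EMG: band-limited tonic noise at the state's RMS,
    plus Poisson-timed multiplicative bursts in wake.  Bit-identical under
    a fixed seed.
    """
    if config.fidelity != "epoch" and config.fidelity != "signal":
        raise ValueError(f"unknown fidelity {config.fidelity!r}")
    if config.fidelity == "epoch":
        raise ValueError(
            "config has epoch fidelity; use generate_band_fractions for the "
            "epoch-level path or set fidelity='signal'"
        )
    if len(hypnogram) == 0:
        raise ValueError("empty hypnogram")
    rng = _as_rng(seed)
    fs = config.sampling_rate
    n_per = int(round(hypnogram.epoch_s * fs))
    n_epochs = len(hypnogram)
    n = n_epochs * n_per
    state_idx = np.empty(n_epochs, dtype=np.int8)
    for i, s in enumerate(STATES):
        state_idx[hypnogram.states == s] = i

    # per-state scale per band: amplitude * sqrt(band fraction)
    gap_w = {k: (hi - lo) for k, (lo, hi) in _GAP_BANDS.items()}
    gap_total = sum(gap_w.values())
    band_rms = {}
    for name in list(_SYNTH_BANDS) + list(_GAP_BANDS):
        per_state = np.empty(3)
        for i, s in enumerate(STATES):
            t = config.band_fractions[s]
            if name in _SYNTH_BANDS:
                frac = t[name]
            else:
                rest = max(1.0 - sum(t.values()), 0.0)
                frac = rest * gap_w[name] / gap_total
            per_state[i] = config.eeg_amplitude[s] * np.sqrt(frac)
        band_rms[name] = per_state

    eeg = np.zeros(n)
    all_bands = {**_SYNTH_BANDS, **_GAP_BANDS}
    for name, band in all_bands.items():
        noise = _band_noise(n, band, fs, rng)
        scale = np.repeat(band_rms[name][state_idx], n_per)
        eeg += noise * scale

    tonic = np.array([config.emg_level[s][0] for s in STATES])
    emg = _band_noise(n, (10.0, 100.0), fs, rng) * np.repeat(tonic[state_idx], n_per)
    burst_len = int(round(_BURST_S * fs))
    for i in range(n_epochs):
        s = STATES[state_idx[i]]
        _, rate_per_min, gain = config.emg_level[s]
        if rate_per_min <= 0 or gain <= 0:
            continue
        k = rng.poisson(rate_per_min * hypnogram.epoch_s / 60.0)
        for start in rng.integers(0, max(n_per - burst_len, 1), size=k):
            lo = i * n_per + int(start)
            emg[lo : lo + burst_len] *= gain
    return Recording(
        eeg=eeg,
        emg=emg,
        sampling_rate=fs,
        start_time=hypnogram.start_time,
        subject_id=hypnogram.subject_id,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _jitter_fractions(config: GeneratorConfig, rng: np.random.Generator) -> dict:
    """Per-animal multiplicative lognormal jitter on state-time targets."""
    cv = config.animal_cv
    out: dict[str, dict[str, float]] = {}
    for phase, fr in config.state_fractions.items():
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv**2))
            mult = rng.lognormal(-(sigma**2) / 2, sigma, size=len(STATES))
        else:
            mult = np.ones(len(STATES))
        vals = np.array([fr.get(s, 0.0) for s in STATES]) * mult
        vals = vals / vals.sum()
        out[phase] = dict(zip(STATES, vals.tolist()))
    return out


def simulate_cohort(
    design: list[tuple[str, int, GeneratorConfig]],
    seed: int,
    duration_s: float = 86400.0,
    start_time: dt.datetime = dt.datetime(2015, 1, 1, 20, 0),
    with_band_fractions: bool = False,
    group_effects: dict | None = None,
) -> list[AnimalData]:
    """Simulate a multi-group cohort with independent per-animal seeds.

    Per-animal seeds derive from the master seed through
    ``numpy.random.SeedSequence.spawn`` (a fixed integer mixing rule), so
    any animal can be regenerated without regenerating the cohort.
    Between-animal variability multiplies each animal's state-time targets
    by lognormal factors with CV ``config.animal_cv``.
    """
    design = list(design)
    if not design or any(n < 1 for _, n, _ in design):
        raise ValueError("cohort design needs at least one group with n >= 1")
    total = sum(n for _, n, _ in design)
    children = np.random.SeedSequence(seed).spawn(total)
    animals: list[AnimalData] = []
    k = 0
    for group, n, config in design:
        for i in range(n):
            rng = np.random.default_rng(children[k])
            k += 1
            targets = _jitter_fractions(config, rng)
            subject = f"{group}_{i + 1:02d}"
            hyp = simulate_hypnogram(
                config, duration_s, start_time, seed=rng,
                subject_id=subject, fractions_override=targets,
            )
            bands = None
            recording = None
            if config.fidelity == "signal":
                recording = synthesize_signals(hyp, config, seed=rng)
            elif with_band_fractions:
                bands = generate_band_fractions(hyp, config, seed=rng)
            truth = PlantedTruth(
                true_hypnogram=hyp,
                true_band_fractions=bands,
                group_effects=dict(group_effects or {}),
                target_fractions=targets,
            )
            animals.append(
                AnimalData(subject_id=subject, group=group, hypnogram=hyp,
                           truth=truth, recording=recording, band_fractions=bands)
            )
    return animals


# ---------------------------------------------------------------------------
# Total sleep deprivation
# ---------------------------------------------------------------------------

def simulate_tsd(
    config: GeneratorConfig,
    tsd_window: tuple[dt.datetime, dt.datetime],
    residual_sleep: dict[str, float],
    duration_s: float = 2 * 86400.0,
    start_time: dt.datetime = dt.datetime(2015, 1, 1, 20, 0),
    rebound_window: tuple[dt.datetime, dt.datetime] | None = None,
    rebound_fractions: dict[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "",
    fractions_override: dict | None = None,
) -> Hypnogram:
    """Simulate a recording containing an enforced-wakefulness window.

    Within ``tsd_window`` the animal is awake except for brief NREM/REM
    intrusions drawn binomially at the configured residual fractions (REM
    intrusions are appended to NREM ones, honoring the REM-entry rule).
    Outside the window, normal semi-Markov dynamics apply; if a
    ``rebound_window`` with ``rebound_fractions`` is given, the state-time
    targets inside it are replaced by the rebound targets.
    """
    res = {s: float(residual_sleep.get(s, 0.0)) for s in ("NR", "R")}
    if min(res.values()) < 0 or sum(res.values()) > 1:
        raise ValueError("residual sleep fractions must be nonnegative and sum to <= 1")
    n_epochs, rem = divmod(duration_s, config.epoch_s)
    if rem:
        raise ValueError("duration is not a multiple of the epoch length")
    n_epochs = int(n_epochs)
    rng = _as_rng(seed)

    def epoch_of(when: dt.datetime) -> int:
        offset = (when - start_time).total_seconds()
        idx = offset / config.epoch_s
        if idx != int(idx):
            raise ValueError(f"window edge {when} does not fall on the epoch grid")
        return int(idx)

    w_lo, w_hi = (epoch_of(t) for t in tsd_window)
    if not (0 <= w_lo < w_hi <= n_epochs):
        raise ValueError("TSD window lies outside the simulated record")
    phase_codes = _phase_codes(start_time, n_epochs, config.epoch_s, config.light_onset)

    segments: list[tuple[int, int, str]] = [(0, w_lo, "normal"), (w_lo, w_hi, "tsd")]
    if rebound_window is not None:
        r_lo, r_hi = (epoch_of(t) for t in rebound_window)
        if not (w_hi <= r_lo < r_hi <= n_epochs):
            raise ValueError("rebound window must follow the TSD window inside the record")
        segments += [(w_hi, r_lo, "normal"), (r_lo, r_hi, "rebound"), (r_hi, n_epochs, "normal")]
    else:
        segments.append((w_hi, n_epochs, "normal"))

    states = np.empty(n_epochs, dtype=np.int8)
    current: int | None = None
    for lo, hi, kind in segments:
        if hi <= lo:
            continue
        if kind == "tsd":
            seg = np.zeros(hi - lo, dtype=np.int8)  # wake
            n_win = hi - lo
            n_nr = rng.binomial(n_win, res["NR"])
            n_r = rng.binomial(n_win, res["R"])
            nr_pos = rng.choice(n_win, size=min(n_nr, n_win), replace=False)
            seg[nr_pos] = 1
            if n_r > 0 and nr_pos.size > 0:
                tail = rng.choice(nr_pos, size=min(n_r, nr_pos.size), replace=False)
                seg[np.minimum(tail + 1, n_win - 1)] = 2
            states[lo:hi] = seg
            current = 0  # leave the window awake
        else:
            override = fractions_override
            if kind == "rebound" and rebound_fractions is not None:
                phases_here = {("light", "dark")[c] for c in np.unique(phase_codes[lo:hi])}
                override = {ph: dict(rebound_fractions) for ph in phases_here}
            states[lo:hi] = _simulate_states(
                config, hi - lo, phase_codes[lo:hi], rng,
                fractions_override=override, initial_state=current,
            )
            current = int(states[hi - 1])
    return Hypnogram(
        states=np.array(STATES, dtype="U2")[states],
        start_time=start_time,
        epoch_s=config.epoch_s,
        subject_id=subject_id or config.group_label,
    )


# ---------------------------------------------------------------------------
# ELISA tables
# ---------------------------------------------------------------------------

def simulate_elisa(
    region_means: dict[str, float],
    cv: float,
    protein_mg_ml: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Synthetic amyloid-beta-42 ELISA readings.

    Per-sample pg/ml values are lognormally dispersed (coefficient of
    variation ``cv``, unit-mean multiplier) around region_mean x protein
    concentration; paired protein concentrations are recorded so that
    downstream normalization recovers the planted pg/mg means.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples per region")
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    if protein_mg_ml <= 0:
        raise ValueError("protein concentration must be positive")
    if min(region_means.values()) <= 0:
        raise ValueError("region means must be positive")
    rng = _as_rng(seed)
    rows = []
    for region, mean_pg_mg in region_means.items():
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv**2))
            mult = rng.lognormal(-(sigma**2) / 2, sigma, size=n)
        else:
            mult = np.ones(n)
        for i in range(n):
            rows.append(
                {
                    "region": region,
                    "sample": f"{region}_{i + 1:02d}",
                    "abeta_pg_ml": mean_pg_mg * protein_mg_ml * mult[i],
                    "protein_mg_ml": protein_mg_ml,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def load_fixture(name: str | Path) -> dict:
    """Load a packaged scenario fixture (e.g. ``"3mo"``) or a YAML path."""
    path = Path(str(name))
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        ref = resources.files("murisomnia") / "fixtures" / f"{name}.yaml"
        if not ref.is_file():
            available = sorted(
                p.name.removesuffix(".yaml")
                for p in (resources.files("murisomnia") / "fixtures").iterdir()
            )
            raise FileNotFoundError(f"no fixture {name!r}; packaged: {available}")
        text = ref.read_text()
    return yaml.safe_load(text)


def config_from_group(spec: dict, label: str, **overrides) -> GeneratorConfig:
    """Build a GeneratorConfig from a fixture group entry."""
    kwargs = dict(
        group_label=label,
        state_fractions=spec["state_fractions"],
        mean_bout_s=spec["mean_bout_s"],
    )
    for key in ("band_fractions", "animal_cv", "band_jitter_cv", "fidelity",
                "epoch_s", "eeg_amplitude"):
        if key in spec:
            kwargs[key] = spec[key]
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)
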