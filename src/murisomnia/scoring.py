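"""Rule-based vigilance-state scoring of raw EEG/EMG.

The scorer operationalizes the standard visual criteria: wake is high-EMG
(or low-amplitude, non-delta, non-theta EEG), NREM sleep is high-delta EEG
with quiet EMG, REM sleep is theta-dominant EEG with a flat (atonic) EMG.
Signals are zero-phase band-passed channel-wise (EEG 0.5-80 Hz, EMG
20-40 Hz), features are computed on 1-s subwindows -- the finest grid on
which both the majority-of-epoch rule and sub-5-s microarousals are well
defined -- and each 5-s epoch takes the label occupying more than half of
its subwindows.

Thresholds are calibrated per recording rather than fixed in microvolts:
EEG/EMG amplitude varies with electrode placement, so each feature's
wake/sleep split point is located adaptively with Otsu's two-cluster
criterion on the (log-scaled, where appropriate) subwindow feature
distribution.  Otsu finds the between-cluster valley regardless of how much
of the recording each state occupies, which a fixed percentile cannot do.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from skimage.filters import threshold_otsu

from .io import Hypnogram, Recording

SUBWINDOW_S = 1.0

#: Feature bands on the 1-s periodogram grid (1-Hz bins).
_DELTA = (0.5, 4.5)
_THETA = (6.0, 10.0)
_TOTAL = (0.125, 100.0)


class CalibrationError(ValueError):
    """The recording's feature distribution is degenerate (e.g. flat EMG)."""


@dataclass
class ScoringThresholds:
    """Per-recording adaptive thresholds.

    ``emg_wake``: subwindow EMG RMS at or above which muscle is active;
    ``emg_atonia``: EMG RMS at or below which the EMG counts as flat;
    ``delta_high``: delta fraction at or above which the EEG is delta-dominant;
    ``theta_ratio_high``: theta/delta ratio at or above which theta dominates;
    ``eeg_amp_low``: EEG RMS below which the EEG counts as low-amplitude;
    ``eeg_amp_high``: EEG RMS at or above which the EEG counts as the
    high-amplitude slow activity of NREM sleep (disabled when the
    recording shows no amplitude bimodality).
    """

    emg_wake: float
    emg_atonia: float
    delta_high: float
    eeg_amp_low: float
    eeg_amp_high: float = float("inf")
    theta_ratio_high: float = 2.0
    calibration: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.emg_atonia < self.emg_wake):
            raise ValueError("need 0 < emg_atonia < emg_wake")
        if min(self.delta_high, self.eeg_amp_low, self.theta_ratio_high) <= 0:
            raise ValueError("all thresholds must be positive")


def bandpass(x: np.ndarray, low_hz: float, high_hz: float,
             sampling_rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass; preserves length."""
    if not 0 < low_hz < high_hz < sampling_rate / 2:
        raise ValueError(f"invalid band [{low_hz}, {high_hz}] at fs={sampling_rate}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def compute_features(recording: Recording, eeg_band: tuple[float, float] = (0.5, 80.0),
                     emg_band: tuple[float, float] = (20.0, 40.0)) -> pd.DataFrame:
    """Per-1-s-subwindow features over the whole recording.

    Returns one row per subwindow with ``eeg_rms``, ``emg_rms``,
    ``delta_fraction``, ``theta_fraction`` and ``theta_delta_ratio``.
    Trailing samples beyond the last whole subwindow are dropped.
    """
    fs = recording.sampling_rate
    n_sub = int(round(SUBWINDOW_S * fs))
    n_windows = recording.n_samples // n_sub
    if n_windows == 0:
        raise ValueError("recording shorter than one subwindow")
    eeg = bandpass(recording.eeg, *eeg_band, fs)
    emg = bandpass(recording.emg, *emg_band, fs)
    eeg_w = eeg[: n_windows * n_sub].reshape(n_windows, n_sub)
    emg_w = emg[: n_windows * n_sub].reshape(n_windows, n_sub)

    freqs, psd = sps.periodogram(eeg_w, fs=fs, window="hann", axis=1)

    def frac(band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        sel = (freqs >= lo) & (freqs < hi)
        return psd[:, sel].sum(axis=1)

    total = frac(_TOTAL)
    total = np.where(total > 0, total, np.nan)
    delta = frac(_DELTA) / total
    theta = frac(_THETA) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / delta, np.inf)
    return pd.DataFrame(
        {
            "eeg_rms": np.sqrt((eeg_w**2).mean(axis=1)),
            "emg_rms": np.sqrt((emg_w**2).mean(axis=1)),
            "delta_fraction": np.nan_to_num(delta),
            "theta_fraction": np.nan_to_num(theta),
            "theta_delta_ratio": ratio,
        }
    )


def classify_subwindows(features: pd.DataFrame, thresholds: ScoringThresholds) -> np.ndarray:
    """Vectorized subwindow classification.

    Precedence: EMG-based wake beats NREM beats REM; anything left over --
    including the low-amplitude non-delta, non-theta EEG signature of quiet
    wake -- defaults to wake.
    """
    cols = ["eeg_rms", "emg_rms", "delta_fraction", "theta_delta_ratio"]
    vals = features[cols].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("NaN feature value")
    eeg_rms, emg_rms, delta, ratio = vals.T
    labels = np.full(features.shape[0], "W", dtype="U2")
    is_w = emg_rms >= thresholds.emg_wake
    # NREM: quiet EMG with either delta dominance or the high-amplitude
    # slow-wave EEG signature (the latter is the lower-variance feature)
    is_nr = ~is_w & (
        (delta >= thresholds.delta_high) | (eeg_rms >= thresholds.eeg_amp_high)
    )
    is_r = (
        ~is_w & ~is_nr
        & (ratio >= thresholds.theta_ratio_high)
        & (emg_rms <= thresholds.emg_atonia)
    )
    labels[is_nr] = "NR"
    labels[is_r] = "R"
    return labels


def classify_subwindow(features: pd.Series | dict, thresholds: ScoringThresholds) -> str:
    """Single-subwindow wrapper around :func:`classify_subwindows`."""
    row = pd.DataFrame([dict(features)])
    return str(classify_subwindows(row, thresholds)[0])


def score_epoch(subwindow_states: list[str] | np.ndarray,
                previous: str | None = None) -> str:
    """Majority-of-epoch rule over exactly five 1-s subwindow labels.

    The label occupying at least 3 of 5 subwindows wins.  When no label
    reaches 3 (a 2/2/1 split), the tie breaks to the previous epoch's state
    if it is among the tied leaders, else to wake.
    """
    labels = list(subwindow_states)
    if len(labels) != 5:
        raise ValueError("an epoch has exactly 5 subwindow labels")
    counts = Counter(labels)
    state, n = counts.most_common(1)[0]
    if n >= 3:
        return state
    leaders = {s for s, c in counts.items() if c == n}
    if previous in leaders:
        return previous
    return "W"


def _split_quality(values: np.ndarray, threshold: float,
                   min_prop: float = 0.02) -> float:
    """Separation score of a candidate split: gap between the two side
    means in units of pooled within-side spread (0 when a side is empty or
    negligibly small)."""
    lo, hi = values[values < threshold], values[values >= threshold]
    n = values.size
    if min(lo.size, hi.size) < max(2, int(min_prop * n)):
        return 0.0
    pooled = np.sqrt((lo.var() * lo.size + hi.var() * hi.size) / n)
    if pooled <= 0:
        return np.inf
    return float((hi.mean() - lo.mean()) / pooled)


#: Default delta-dominance cutoff when a recording shows no bimodal delta
#: distribution (single-state recordings): delta holds over a third of
#: total power.
DELTA_DOMINANT = 0.35

# An Otsu split of a single Gaussian scores ~2.7 gap-over-pooled-spread;
# require clearly more before trusting a split with no corroborating
# evidence from another feature.
_MIN_SEPARATION = 3.0

# NREM evidence: the high-delta and high-amplitude subwindow sets must
# overlap this much (Jaccard) to count as a real NREM cluster.  Spurious
# splits of unimodal noise overlap near chance (~0.3-0.45); genuine NREM
# overlaps above 0.8.
_MIN_NREM_CONSENSUS = 0.6

# A candidate EMG wake threshold may fire in at most this fraction of the
# EEG-identified sleep subwindows.
_MAX_SLEEP_CONFLICT = 0.1


def calibrate_thresholds(recording: Recording, min_duration_s: float = 1800.0,
                         theta_ratio_high: float = 2.0) -> ScoringThresholds:
    """Per-recording adaptive thresholds from subwindow feature distributions.

    The log EMG RMS distribution is trimodal in a full recording (REM
    atonia << NREM tone < active wake), so it is split with a three-class
    Otsu first; each candidate threshold is kept only if it separates two
    well-populated clusters (gap well above what a unimodal
    distribution produces).  When the EMG
    carries no usable wake/sleep split (single-state recordings), EMG-based
    wake detection is disabled (threshold above the observed range) and
    classification falls back to the EEG rules; when the delta-fraction
    distribution is not bimodal, delta dominance defaults to the fixed
    0.35 cutoff.  Deterministic: repeated calls yield identical thresholds.
    """
    if recording.duration_s < min_duration_s:
        raise ValueError(
            f"calibration needs >= {min_duration_s:.0f} s of signal, "
            f"got {recording.duration_s:.0f} s"
        )
    feats = compute_features(recording)
    emg = feats["emg_rms"].to_numpy()
    if emg.max() <= 0 or np.ptp(np.log(np.maximum(emg, 1e-12))) < 1e-6:
        raise CalibrationError("EMG is flat; cannot separate wake from sleep")
    log_emg = np.log(np.maximum(emg, 1e-12))
    notes: dict = {}

    def otsu_or_none(values: np.ndarray) -> float | None:
        try:
            return float(threshold_otsu(values, nbins=256))
        except ValueError:
            return None

    # NREM evidence: delta dominance and high EEG amplitude must pick out
    # (mostly) the same subwindows
    delta = feats["delta_fraction"].to_numpy()
    log_eeg = np.log(np.maximum(feats["eeg_rms"].to_numpy(), 1e-12))
    cand_delta = otsu_or_none(delta)
    cand_amp = otsu_or_none(log_eeg)
    sleep_mask = None
    if cand_delta is not None and cand_amp is not None:
        high_delta = delta >= cand_delta
        high_amp = log_eeg >= cand_amp
        union = int((high_delta | high_amp).sum())
        jaccard = (high_delta & high_amp).sum() / union if union else 0.0
        notes["nrem_consensus"] = round(float(jaccard), 3)
        if jaccard >= _MIN_NREM_CONSENSUS:
            sleep_mask = high_delta | high_amp
    if sleep_mask is not None:
        delta_high = cand_delta
        eeg_amp_high = float(np.exp(cand_amp))
        eeg_amp_low = eeg_amp_high
        notes["nrem"] = "otsu (delta/amplitude consensus)"
    else:
        delta_high = DELTA_DOMINANT
        eeg_amp_high = float("inf")
        eeg_amp_low = float(np.median(feats["eeg_rms"]))
        notes["nrem"] = f"fixed delta cutoff {DELTA_DOMINANT} (no NREM cluster)"

    # EMG wake threshold: candidate splits from a three-class (atonia /
    # sleep tone / wake) and a two-class decomposition
    candidates: list[float] = []
    try:
        from skimage.filters import threshold_multiotsu

        candidates += list(threshold_multiotsu(log_emg, classes=3, nbins=256))
    except ValueError:
        pass
    cand2 = otsu_or_none(log_emg)
    if cand2 is not None:
        candidates.append(cand2)
    candidates = sorted(set(candidates))
    emg_wake = None
    if sleep_mask is not None and sleep_mask.any():
        # most sensitive threshold that stays quiet during EEG-defined sleep
        valid = [
            t for t in candidates
            if np.mean(log_emg[sleep_mask] >= t) <= _MAX_SLEEP_CONFLICT
            and np.mean(log_emg >= t) >= 0.02
        ]
        if valid:
            emg_wake = float(np.exp(min(valid)))
            notes["emg_wake"] = "otsu (sleep-consistent)"
    else:
        valid = [t for t in candidates if _split_quality(log_emg, t) >= _MIN_SEPARATION]
        if valid:
            emg_wake = float(np.exp(max(valid)))
            notes["emg_wake"] = "otsu (separation)"
    if emg_wake is None:
        # no usable wake/sleep EMG structure: disable EMG-based wake
        emg_wake = float(np.exp(log_emg.max() + 1.0))
        notes["emg_wake"] = "disabled"

    lower = [t for t in candidates if np.exp(t) < emg_wake * 0.999]
    if lower:
        emg_atonia = float(np.exp(min(lower)))
        notes["emg_atonia"] = "otsu"
    else:
        below = log_emg[log_emg < np.log(emg_wake)]
        base = below if below.size >= 10 else log_emg
        emg_atonia = float(np.exp(np.percentile(base, 5)))
        notes["emg_atonia"] = "5th percentile fallback"
    notes["n_subwindows"] = int(feats.shape[0])

    return ScoringThresholds(
        emg_wake=emg_wake,
        emg_atonia=min(emg_atonia, emg_wake * 0.999),
        delta_high=delta_high,
        eeg_amp_low=eeg_amp_low,
        eeg_amp_high=eeg_amp_high,
        theta_ratio_high=theta_ratio_high,
        calibration=notes,
    )


def score_recording(
    recording: Recording,
    thresholds: ScoringThresholds | None = None,
    epoch_s: float = 5.0,
    return_subwindows: bool = False,
):
    """Score a recording into a hypnogram.

    Pipeline: channel-wise band-pass, 1-s subwindow features, rule-based
    subwindow classification, majority-of-epoch rule with previous-state
    tie-break.  A trailing partial epoch is dropped.  Thresholds are
    auto-calibrated when absent.
    """
    if thresholds is None:
        thresholds = calibrate_thresholds(recording)
    feats = compute_features(recording)
    sub_labels = classify_subwindows(feats, thresholds)
    per_epoch = int(round(epoch_s / SUBWINDOW_S))
    n_epochs = sub_labels.size // per_epoch
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    states = np.empty(n_epochs, dtype="U2")
    previous: str | None = None
    for i in range(n_epochs):
        states[i] = score_epoch(sub_labels[i * per_epoch : (i + 1) * per_epoch], previous)
        previous = states[i]
    hyp = Hypnogram(states=states, start_time=recording.start_time,
                    epoch_s=epoch_s, subject_id=recording.subject_id)
    if return_subwindows:
        return hyp, sub_labels
    return hyp


@dataclass(frozen=True)
class Microarousal:
    onset_s: float
    duration_s: float


def detect_microarousals(subwindow_labels: np.ndarray | list[str],
                         subwindow_s: float = SUBWINDOW_S) -> list[Microarousal]:
    """Brief wake intrusions: maximal W runs of 1-4 subwindows (< 5 s)
    flanked by sleep on both sides.  Runs touching either end of the stream
    are excluded; epoch labels are not altered."""
    labels = np.asarray(subwindow_labels, dtype="U2")
    events: list[Microarousal] = []
    n = labels.size
    i = 0
    while i < n:
        if labels[i] != "W":
            i += 1
            continue
        j = i
        while j < n and labels[j] == "W":
            j += 1
        run = j - i
        if 1 <= run <= 4 and i > 0 and j < n:
            events.append(Microarousal(onset_s=i * subwindow_s,
                                       duration_s=run * subwindow_s))
        i = j
    return events
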