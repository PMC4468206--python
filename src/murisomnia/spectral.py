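"""Reporting-grade spectral analysis of scored EEG.

Each 5-s epoch (2560 samples at 512 Hz) is Hanning-windowed, zero-padded to
an FFT size of 4096 and turned into a power spectrum on a 0.125-Hz grid over
0.125-100 Hz (800 bins).  Spectra are normalized to the summed power over
that full range, which removes electrode-placement amplitude differences;
band powers are then fractions of total power.

Band edges are half-open ``[low, high)`` so adjacent bands never share a
bin.  The canonical reporting bands are delta 0.5-4.5, theta 6-10, alpha
10-14, beta 14-20 and low gamma 20-50 Hz, plus the narrower 7-10 Hz REM
theta band used for REM-sleep quantification.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .io import LIGHT_ONSET, Hypnogram, Recording

FFT_SIZE = 4096
SAMPLING_RATE = 512.0
BIN_HZ = SAMPLING_RATE / FFT_SIZE  # 0.125 Hz
N_BINS = 800  # 0.125 .. 100 Hz inclusive


class EmptyStateError(ValueError):
    """No epochs of the requested state exist within the requested phase."""


@dataclass(frozen=True)
class Band:
    """A half-open frequency band [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"invalid band {self.name}: [{self.low_hz}, {self.high_hz})")

    def bin_slice(self) -> slice:
        """Index slice into an 800-bin spectrum (bin k holds k*0.125 Hz)."""
        k_lo = int(np.ceil(self.low_hz / BIN_HZ))
        k_hi = int(np.ceil(self.high_hz / BIN_HZ))  # exclusive
        k_lo = max(k_lo, 1)
        k_hi = min(k_hi, N_BINS + 1)
        return slice(k_lo - 1, k_hi - 1)


DELTA = Band("delta", 0.5, 4.5)
THETA = Band("theta", 6.0, 10.0)
REM_THETA = Band("rem_theta", 7.0, 10.0)
ALPHA = Band("alpha", 10.0, 14.0)
BETA = Band("beta", 14.0, 20.0)
LOW_GAMMA = Band("low_gamma", 20.0, 50.0)

#: All named bands, including the overlapping REM theta variant.
BANDS: dict[str, Band] = {
    b.name: b for b in (DELTA, THETA, REM_THETA, ALPHA, BETA, LOW_GAMMA)
}

#: The disjoint canonical reporting set (gaps remain at 4.5-6 and 50-100 Hz).
CANONICAL_BANDS: tuple[Band, ...] = (DELTA, THETA, ALPHA, BETA, LOW_GAMMA)


@dataclass
class PowerSpectrum:
    """Power at frequencies k*0.125 Hz for k = 1..800."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise ValueError(f"spectrum must have exactly {N_BINS} bins")
        if (self.values < 0).any():
            raise ValueError("spectral power must be nonnegative")

    @property
    def freqs(self) -> np.ndarray:
        return BIN_HZ * np.arange(1, N_BINS + 1)


def epoch_psd(eeg_epoch: np.ndarray, sampling_rate: float = SAMPLING_RATE,
              epoch_s: float = 5.0) -> PowerSpectrum:
    """Un-normalized power spectrum of one epoch.

    The epoch must contain exactly ``epoch_s * sampling_rate`` samples and
    the sampling rate must be 512 Hz so that the 4096-point FFT lands on the
    0.125-Hz reporting grid.
    """
    if sampling_rate != SAMPLING_RATE:
        raise ValueError("the 0.125-Hz reporting grid requires 512 Hz input")
    x = np.asarray(eeg_epoch, dtype=float)
    n = int(round(epoch_s * sampling_rate))
    if x.shape != (n,):
        raise ValueError(f"epoch must contain exactly {n} samples, got {x.shape}")
    w = np.hanning(n)
    spec = np.fft.rfft(x * w, FFT_SIZE)
    # coherent-gain correction for the Hanning window (constant factor;
    # cancels under normalization but kept for un-normalized outputs)
    psd = np.abs(spec) ** 2 / (w.mean() ** 2 * n**2)
    return PowerSpectrum(values=psd[1 : N_BINS + 1], normalized=False)


def normalize_spectrum(ps: PowerSpectrum) -> PowerSpectrum:
    """Divide by the summed power over 0.125-100 Hz (idempotent)."""
    total = ps.values.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return PowerSpectrum(values=ps.values / total, normalized=True)


def band_power(ps: PowerSpectrum, band: Band | str) -> float:
    """Fraction of total power within ``band`` (normalized input required)."""
    if not ps.normalized:
        raise ValueError("band_power expects a normalized spectrum")
    if isinstance(band, str):
        band = BANDS[band]
    return float(ps.values[band.bin_slice()].sum())


def band_fractions(ps: PowerSpectrum) -> dict[str, float]:
    """Fractions for the disjoint canonical band set."""
    return {b.name: band_power(ps, b) for b in CANONICAL_BANDS}


def state_phase_spectrum(
    recording: Recording,
    hypnogram: Hypnogram,
    state: str,
    phase: str,
    light_onset: dt.time = LIGHT_ONSET,
) -> PowerSpectrum:
    """Mean normalized spectrum over all epochs of ``state`` within ``phase``.

    The mean of unit-sum vectors is itself unit-sum, so the result remains
    normalized.
    """
    from .architecture import split_phases  # local import to avoid a cycle

    phases = split_phases(hypnogram, light_onset)
    n_per_epoch = int(round(hypnogram.epoch_s * recording.sampling_rate))
    n_epochs = min(len(hypnogram), recording.n_samples // n_per_epoch)
    acc = np.zeros(N_BINS)
    count = 0
    for i in range(n_epochs):
        if hypnogram.states[i] != state or phases[i] != phase:
            continue
        seg = recording.eeg[i * n_per_epoch : (i + 1) * n_per_epoch]
        acc += normalize_spectrum(epoch_psd(seg, recording.sampling_rate,
                                            hypnogram.epoch_s)).values
        count += 1
    if count == 0:
        raise EmptyStateError(f"no {state} epochs in the {phase} phase")
    return PowerSpectrum(values=acc / count, normalized=True)


def mean_spectrum(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Mean of normalized spectra (remains normalized)."""
    if not spectra:
        raise EmptyStateError("no spectra to average")
    if not all(ps.normalized for ps in spectra):
        raise ValueError("mean_spectrum expects normalized spectra")
    return PowerSpectrum(np.mean([ps.values for ps in spectra], axis=0),
                         normalized=True)


# gap regions of the disjoint canonical set, used when expanding band
# fractions back into a full spectrum
_GAPS: tuple[Band, ...] = (
    Band("infra", 0.125, 0.5),
    Band("delta_theta_gap", 4.5, 6.0),
    Band("high", 50.0, 100.0 + BIN_HZ),
)


def spectrum_from_band_fractions(fractions: dict[str, float]) -> PowerSpectrum:
    """Expand canonical band fractions into a flat-in-band 800-bin spectrum.

    Power within each canonical band is spread uniformly over its bins; any
    remainder (1 - sum of the five canonical fractions) is spread over the
    gap regions proportionally to their widths.  Used by the epoch-fidelity
    synthetic path, where per-epoch band fractions are generated directly.
    """
    values = np.zeros(N_BINS)
    total = 0.0
    for b in CANONICAL_BANDS:
        f = float(fractions[b.name])
        if f < 0:
            raise ValueError(f"negative band fraction for {b.name}")
        sl = b.bin_slice()
        values[sl] = f / (sl.stop - sl.start)
        total += f
    rest = 1.0 - total
    if rest < -1e-9:
        raise ValueError("canonical band fractions exceed 1")
    rest = max(rest, 0.0)
    gap_bins = sum(g.bin_slice().stop - g.bin_slice().start for g in _GAPS)
    for g in _GAPS:
        sl = g.bin_slice()
        values[sl] = rest / gap_bins
    return PowerSpectrum(values=values / values.sum(), normalized=True)
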