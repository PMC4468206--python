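"""Recording and hypnogram containers plus on-disk formats.

Raw two-channel (EEG, EMG) recordings travel as European Data Format (EDF)
files: a fixed-layout ASCII header followed by little-endian 16-bit data
records.  Hypnograms travel as plain CSV with an explicit epoch index and
clock time, one row per 5-s epoch.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Canonical vigilance-state labels: wake, NREM sleep, REM sleep.
STATES: tuple[str, ...] = ("W", "NR", "R")

#: Default light/dark schedule: lights on 08:00, off 20:00 (12-12 cycle).
LIGHT_ONSET = dt.time(8, 0)

#: Default per-channel physical ranges for EDF export, in microvolts.
DEFAULT_PHYSICAL_RANGE = {"EEG": 500.0, "EMG": 1000.0}

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


class ChannelError(ValueError):
    """An expected labeled channel is missing from an EDF file."""


class FormatError(ValueError):
    """A file does not parse as the expected on-disk format."""


@dataclass
class Recording:
    """A two-channel polysomnographic recording in physical units (µV)."""

    eeg: np.ndarray
    emg: np.ndarray
    sampling_rate: float
    start_time: dt.datetime
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape or self.eeg.ndim != 1:
            raise ValueError("eeg and emg must be 1-D arrays of equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.eeg.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Hypnogram:
    """Vigilance-state labels on a fixed epoch grid (default 5 s)."""

    states: np.ndarray
    start_time: dt.datetime
    epoch_s: float = 5.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="U2")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")

    def __len__(self) -> int:
        return self.states.size

    @property
    def duration_s(self) -> float:
        return len(self) * self.epoch_s

    def epoch_start_times(self) -> np.ndarray:
        """Clock time of each epoch's first sample."""
        step = dt.timedelta(seconds=self.epoch_s)
        return np.array([self.start_time + i * step for i in range(len(self))])


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def write_edf(
    recording: Recording,
    path: str | Path,
    physical_range: dict[str, float] | None = None,
) -> int:
    """Write a recording as a two-signal EDF file with 1-s data records.

    Samples outside the per-channel physical range are clipped; the number
    of clipped samples is returned.  The sampling rate must be an integer
    and the duration a whole number of seconds.
    """
    pr = dict(DEFAULT_PHYSICAL_RANGE)
    if physical_range:
        pr.update(physical_range)
    fs = recording.sampling_rate
    if fs != int(fs):
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(fs)
    if recording.n_samples % fs != 0:
        raise ValueError("EDF export requires a whole number of seconds")
    if not (np.isfinite(recording.eeg).all() and np.isfinite(recording.emg).all()):
        raise ValueError("non-finite sample values cannot be written to EDF")
    n_records = recording.n_samples // fs

    channels = [("EEG", recording.eeg, pr["EEG"]), ("EMG", recording.emg, pr["EMG"])]
    n_clipped = 0
    digital = []
    for _, sig, rng in channels:
        clipped = np.clip(sig, -rng, rng)
        n_clipped += int(np.sum(clipped != sig))
        # linear map [-rng, rng] -> [dig_min, dig_max]
        d = np.round(
            (clipped + rng) / (2 * rng) * (_EDF_DIG_MAX - _EDF_DIG_MIN) + _EDF_DIG_MIN
        ).astype("<i2")
        digital.append(d)

    t0 = recording.start_time
    header = b"".join(
        [
            _pad("0", 8),
            _pad(recording.subject_id or "X", 80),
            _pad("Startdate " + t0.strftime("%d-%b-%Y").upper(), 80),
            _pad(t0.strftime("%d.%m.%y"), 8),
            _pad(t0.strftime("%H.%M.%S"), 8),
            _pad(str(256 * 3), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad("2", 4),
        ]
    )
    # EDF signal headers are field-major: all labels, then all transducers, ...
    fields = [
        ([name for name, _, _ in channels], 16),
        (["" for _ in channels], 80),
        (["uV" for _ in channels], 8),
        ([f"{-rng:g}" for _, _, rng in channels], 8),
        ([f"{rng:g}" for _, _, rng in channels], 8),
        ([str(_EDF_DIG_MIN) for _ in channels], 8),
        ([str(_EDF_DIG_MAX) for _ in channels], 8),
        (["" for _ in channels], 80),
        ([str(fs) for _ in channels], 8),
        (["" for _ in channels], 32),
    ]
    sig_header = b"".join(_pad(v, w) for values, w in fields for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in range(n_records):
            for d in digital:
                fh.write(d[rec * fs : (rec + 1) * fs].tobytes())
    return n_clipped


def read_edf(
    path: str | Path,
    label_map: dict[str, str] | None = None,
) -> Recording:
    """Read a two-channel EDF file back into physical units.

    ``label_map`` maps the roles ``"eeg"``/``"emg"`` to channel-label
    substrings (case-insensitive); defaults to ``{"eeg": "EEG", "emg": "EMG"}``.
    """
    label_map = label_map or {"eeg": "EEG", "emg": "EMG"}
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            day, month, year = (int(x) for x in head[168:176].decode("ascii").split("."))
            hh, mm, ss = (int(x) for x in head[176:184].decode("ascii").split("."))
            n_records = int(head[236:244])
            record_s = float(head[244:252])
            ns = int(head[252:256])
        except (ValueError, UnicodeDecodeError) as exc:
            raise FormatError(f"{path}: corrupt EDF header ({exc})") from exc
        year += 2000 if year < 85 else 1900
        start = dt.datetime(year, month, day, hh, mm, ss)

        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise FormatError(f"{path}: truncated EDF signal header")

        # byte offsets of each field block (the signal header is field-major)
        off = np.cumsum([0, 16, 80, 8, 8, 8, 8, 8, 80, 8])

        def fcol(k: int, width: int) -> list[str]:
            base = off[k] * ns
            return [sig[base + i * width : base + (i + 1) * width].decode().strip() for i in range(ns)]

        labels = fcol(0, 16)
        phys_min = [float(x) for x in fcol(3, 8)]
        phys_max = [float(x) for x in fcol(4, 8)]
        dig_min = [int(x) for x in fcol(5, 8)]
        dig_max = [int(x) for x in fcol(6, 8)]
        n_samp = [int(x) for x in fcol(8, 8)]

        data = np.frombuffer(fh.read(), dtype="<i2")

    per_record = sum(n_samp)
    if data.size < per_record * n_records:
        raise FormatError(f"{path}: EDF data shorter than header declares")
    data = data[: per_record * n_records].reshape(n_records, per_record)

    signals = {}
    pos = 0
    for i, label in enumerate(labels):
        chunk = data[:, pos : pos + n_samp[i]].reshape(-1).astype(float)
        pos += n_samp[i]
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        signals[label.upper()] = phys_min[i] + (chunk - dig_min[i]) * gain

    def find(role: str) -> np.ndarray:
        want = label_map[role].upper()
        for label, samples in signals.items():
            if want in label:
                return samples
        raise ChannelError(f"{path}: no channel label matching {label_map[role]!r}")

    eeg, emg = find("eeg"), find("emg")
    fs = n_samp[0] / record_s
    return Recording(eeg=eeg, emg=emg, sampling_rate=fs, start_time=start,
                     subject_id=path.stem)


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

_CSV_HEADER = ["epoch_index", "start_clock", "state"]


def write_hypnogram(hypnogram: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram as ``epoch_index,start_clock,state`` CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        t0 = hypnogram.start_time
        for i, state in enumerate(hypnogram.states):
            clock = t0 + dt.timedelta(seconds=i * hypnogram.epoch_s)
            writer.writerow([i, clock.isoformat(), state])


def read_hypnogram(path: str | Path, epoch_s: float = 5.0) -> Hypnogram:
    """Read a hypnogram CSV written by :func:`write_hypnogram`."""
    path = Path(path)
    states: list[str] = []
    start: dt.datetime | None = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _CSV_HEADER:
            raise FormatError(f"{path}: expected header {_CSV_HEADER}, got {header}")
        for row_no, row in enumerate(reader):
            idx, clock, state = row
            if int(idx) != row_no:
                raise FormatError(
                    f"{path}: non-contiguous epoch index {idx} at row {row_no + 2}"
                )
            if state not in STATES:
                raise FormatError(
                    f"{path}: unknown state token {state!r} at row {row_no + 2}"
                )
            when = dt.datetime.fromisoformat(clock)
            if start is None:
                start = when
            states.append(state)
    if start is None:
        raise FormatError(f"{path}: empty hypnogram file")
    return Hypnogram(states=np.array(states), start_time=start, epoch_s=epoch_s,
                     subject_id=path.stem)
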