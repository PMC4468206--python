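"""Sleep-architecture metrics computed from hypnograms.

Every metric operates on the 5-s epoch grid.  Epochs are assigned to the
light (08:00-20:00) or dark (20:00-08:00) phase by the clock time of their
first sample.  An *episode* (bout) is a maximal run of consecutive epochs in
one state; a *transition* to state X is an epoch labeled X whose predecessor
differs (the recording's first epoch is never counted, which makes
transition counts agree with episode counts to within the boundary episode).
Episodes that span the phase boundary belong to the phase of their first
epoch and are not split.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LIGHT_ONSET, Hypnogram, STATES

PHASES = ("light", "dark")


@dataclass(frozen=True)
class Episode:
    state: str
    start_epoch: int
    length_epochs: int
    epoch_s: float = 5.0

    @property
    def duration_s(self) -> float:
        return self.length_epochs * self.epoch_s


@dataclass
class ArchitectureSummary:
    """Per phase x state percent time, bout statistics and transitions."""

    table: pd.DataFrame  # index (phase, state); percent_time, mean_episode_s, n_transitions
    hourly_minutes: pd.DataFrame  # index clock hour 0..23, columns W/NR/R
    subject_id: str = ""


def split_phases(hypnogram: Hypnogram, light_onset: dt.time = LIGHT_ONSET) -> np.ndarray:
    """Phase label ('light'/'dark') of each epoch by its start clock time."""
    on = light_onset.hour * 3600 + light_onset.minute * 60 + light_onset.second
    off = (on + 12 * 3600) % 86400
    t0 = hypnogram.start_time
    sec0 = t0.hour * 3600 + t0.minute * 60 + t0.second
    secs = (sec0 + hypnogram.epoch_s * np.arange(len(hypnogram))) % 86400
    if on < off:
        light = (secs >= on) & (secs < off)
    else:
        light = (secs >= on) | (secs < off)
    return np.where(light, "light", "dark")


def percent_time(hypnogram: Hypnogram, phase: str, state: str,
                 light_onset: dt.time = LIGHT_ONSET) -> float:
    """100 x (epochs of ``state`` in ``phase``) / (epochs in ``phase``)."""
    phases = split_phases(hypnogram, light_onset)
    mask = phases == phase
    if not mask.any():
        raise ValueError(f"hypnogram contains no {phase}-phase epochs")
    return 100.0 * float(np.mean(hypnogram.states[mask] == state))


def segment_episodes(hypnogram: Hypnogram) -> list[Episode]:
    """Run-length encode the hypnogram into maximal single-state episodes."""
    states = hypnogram.states
    if states.size == 0:
        raise ValueError("empty hypnogram")
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    return [
        Episode(state=str(states[s]), start_epoch=int(s), length_epochs=int(e - s),
                epoch_s=hypnogram.epoch_s)
        for s, e in zip(starts, ends)
    ]


def mean_episode_duration(
    episodes: list[Episode],
    state: str,
    phase: str | None = None,
    phases: np.ndarray | None = None,
) -> float:
    """Mean duration (s) of ``state`` episodes, optionally restricted to the
    phase of the episode's first epoch.  Returns NaN when none qualify."""
    durations = [
        ep.duration_s
        for ep in episodes
        if ep.state == state and (phase is None or phases[ep.start_epoch] == phase)
    ]
    if not durations:
        return float("nan")
    return float(np.mean(durations))


def count_transitions(hypnogram: Hypnogram, state: str, phase: str | None = None,
                      light_onset: dt.time = LIGHT_ONSET) -> int:
    """Entries into ``state``: epochs labeled ``state`` whose predecessor
    differs.  The first epoch of the recording is never counted."""
    states = hypnogram.states
    if states.size == 0:
        raise ValueError("empty hypnogram")
    entry = np.zeros(states.size, dtype=bool)
    entry[1:] = (states[1:] == state) & (states[:-1] != state)
    if phase is not None:
        entry &= split_phases(hypnogram, light_onset) == phase
    return int(entry.sum())


def hourly_timecourse(hypnogram: Hypnogram) -> pd.DataFrame:
    """Minutes per state per clock hour (0-23).  Hours sharing epochs from
    several calendar days accumulate; per-hour totals equal the recorded
    minutes of that hour."""
    if len(hypnogram) == 0:
        raise ValueError("empty hypnogram")
    t0 = hypnogram.start_time
    sec0 = t0.hour * 3600 + t0.minute * 60 + t0.second
    hours = ((sec0 + hypnogram.epoch_s * np.arange(len(hypnogram))) % 86400 // 3600).astype(int)
    out = pd.DataFrame(0.0, index=pd.RangeIndex(24, name="hour"), columns=list(STATES))
    for state in STATES:
        counts = np.bincount(hours[hypnogram.states == state], minlength=24)
        out[state] = counts * hypnogram.epoch_s / 60.0
    return out


def summarize(hypnogram: Hypnogram, light_onset: dt.time = LIGHT_ONSET) -> ArchitectureSummary:
    """Full per-phase, per-state architecture summary for one subject."""
    phases = split_phases(hypnogram, light_onset)
    episodes = segment_episodes(hypnogram)
    rows = []
    for phase in PHASES:
        if not (phases == phase).any():
            continue
        for state in STATES:
            rows.append(
                {
                    "phase": phase,
                    "state": state,
                    "percent_time": percent_time(hypnogram, phase, state, light_onset),
                    "mean_episode_s": mean_episode_duration(episodes, state, phase, phases),
                    "n_transitions": count_transitions(hypnogram, state, phase, light_onset),
                }
            )
    table = pd.DataFrame(rows).set_index(["phase", "state"])
    return ArchitectureSummary(
        table=table,
        hourly_minutes=hourly_timecourse(hypnogram),
        subject_id=hypnogram.subject_id,
    )


def circadian_contrast(summary: ArchitectureSummary) -> dict[str, float]:
    """Dark-minus-light percent-time difference per state for one subject."""
    table = summary.table
    for phase in PHASES:
        if phase not in table.index.get_level_values("phase"):
            raise ValueError(f"summary is missing the {phase} phase")
    return {
        state: float(
            table.loc[("dark", state), "percent_time"]
            - table.loc[("light", state), "percent_time"]
        )
        for state in STATES
    }
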