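"""Experiment-specific analyses: sleep-deprivation rebound, drug treatment
windows, and region-wise amyloid-beta-42 ELISA normalization.

Windows are half-open clock intervals ``[start, end)`` aligned to the epoch
grid.  The deprivation design pairs a 6-h enforced-wakefulness window
(light onset to mid-light, day 2) with the 2-h recovery window immediately
after it and a circadian-matched 2-h baseline window on day 1, so the
rebound comparison is free of circadian confound.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Hypnogram, STATES
from .spectral import DELTA, PowerSpectrum, band_power


@dataclass(frozen=True)
class DeprivationDesign:
    """Windows for the total-sleep-deprivation (TSD) rebound analysis."""

    baseline_window: tuple[dt.datetime, dt.datetime]
    tsd_window: tuple[dt.datetime, dt.datetime]
    rebound_window: tuple[dt.datetime, dt.datetime]

    def __post_init__(self) -> None:
        if self.rebound_window[0] != self.tsd_window[1]:
            raise ValueError("rebound window must immediately follow the TSD window")
        b = self.baseline_window[1] - self.baseline_window[0]
        r = self.rebound_window[1] - self.rebound_window[0]
        if b != r:
            raise ValueError("baseline and rebound windows must have equal length")
        if (self.baseline_window[0].time() != self.rebound_window[0].time()):
            raise ValueError("baseline window must be clock-matched to the rebound window")

    @classmethod
    def standard(cls, start_date: dt.date) -> "DeprivationDesign":
        """Windows for a 48-h record starting 20:00 on ``start_date``.

        The baseline day runs through the following evening; deprivation
        starts at the light onset after that (6 h), immediately followed by
        the 2-h rebound window; the baseline window is the clock-matched
        14:00-16:00 interval of the baseline day's light phase.
        """
        base_day = start_date + dt.timedelta(days=1)
        tsd_day = start_date + dt.timedelta(days=2)
        t = dt.datetime.combine
        return cls(
            baseline_window=(t(base_day, dt.time(14, 0)), t(base_day, dt.time(16, 0))),
            tsd_window=(t(tsd_day, dt.time(8, 0)), t(tsd_day, dt.time(14, 0))),
            rebound_window=(t(tsd_day, dt.time(14, 0)), t(tsd_day, dt.time(16, 0))),
        )


@dataclass(frozen=True)
class TreatmentRecord:
    """One animal's drug-treatment session (dose in mg/kg, 0 = vehicle)."""

    dose: float
    injection_time: dt.datetime
    analysis_window_h: float = 2.0

    @property
    def window(self) -> tuple[dt.datetime, dt.datetime]:
        return (
            self.injection_time,
            self.injection_time + dt.timedelta(hours=self.analysis_window_h),
        )


def _window_slice(hypnogram: Hypnogram, window: tuple[dt.datetime, dt.datetime]) -> slice:
    lo_s = (window[0] - hypnogram.start_time).total_seconds()
    hi_s = (window[1] - hypnogram.start_time).total_seconds()
    lo, hi = lo_s / hypnogram.epoch_s, hi_s / hypnogram.epoch_s
    if lo != int(lo) or hi != int(hi):
        raise ValueError("window edges must fall on the epoch grid")
    lo, hi = int(lo), int(hi)
    if not (0 <= lo < hi <= len(hypnogram)):
        raise ValueError(
            f"window [{window[0]} .. {window[1]}) is not covered by the hypnogram"
        )
    return slice(lo, hi)


def window_percentages(hypnogram: Hypnogram,
                       window: tuple[dt.datetime, dt.datetime]) -> dict[str, float]:
    """Percent time per vigilance state within a clock window."""
    sl = _window_slice(hypnogram, window)
    states = hypnogram.states[sl]
    return {s: 100.0 * float(np.mean(states == s)) for s in STATES}


def tsd_efficacy(
    hypnogram: Hypnogram,
    tsd_window: tuple[dt.datetime, dt.datetime],
    wake_threshold: float = 96.0,
) -> dict:
    """Composition of the deprivation window, with an efficacy flag.

    Effective deprivation keeps the animal awake for at least
    ``wake_threshold`` percent of the window (default 96 %, matching what
    gentle handling achieves in practice).
    """
    pct = window_percentages(hypnogram, tsd_window)
    return {**pct, "efficacious": pct["W"] >= wake_threshold}


def rebound_delta_shift(baseline_nrem_spectrum: PowerSpectrum,
                        rebound_nrem_spectrum: PowerSpectrum) -> float:
    """Percent change in normalized NREM delta power, rebound vs baseline.

    100 x (delta_rebound - delta_baseline) / delta_baseline; invariant to
    common rescaling because both inputs are normalized spectra.
    """
    d_base = band_power(baseline_nrem_spectrum, DELTA)
    d_reb = band_power(rebound_nrem_spectrum, DELTA)
    if d_base <= 0:
        raise ValueError("baseline delta power is zero; shift undefined")
    return 100.0 * (d_reb - d_base) / d_base


def rebound_duration_change(hypnogram: Hypnogram,
                            design: DeprivationDesign) -> pd.DataFrame:
    """Paired per-state percentages for the baseline and rebound windows.

    One row per state with ``baseline`` and ``rebound`` percent-time
    columns, ready to stack across subjects for the mixed ANOVA.
    """
    base = window_percentages(hypnogram, design.baseline_window)
    reb = window_percentages(hypnogram, design.rebound_window)
    return pd.DataFrame(
        {"state": list(STATES),
         "baseline": [base[s] for s in STATES],
         "rebound": [reb[s] for s in STATES]}
    ).set_index("state")


def treatment_window_summary(hypnogram: Hypnogram,
                             record: TreatmentRecord) -> dict[str, float]:
    """Percent time per state in the post-injection analysis window."""
    return window_percentages(hypnogram, record.window)


def dose_contrast(summaries: pd.DataFrame, dose: float, vehicle: float = 0.0,
                  state: str = "NR") -> tuple[dict[str, float], pd.DataFrame]:
    """Group-mean percent-time change (dose minus vehicle) per genotype.

    ``summaries`` is tidy with columns ``genotype``, ``dose``, ``subject``
    and one column per state.  Returns the per-genotype contrast for
    ``state`` and the two-dose subset forwarded to the two-way ANOVA.
    """
    needed = {"genotype", "dose", "subject", state}
    missing = needed - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries table is missing columns {sorted(missing)}")
    subset = summaries[summaries["dose"].isin([dose, vehicle])].copy()
    contrasts: dict[str, float] = {}
    for genotype, grp in subset.groupby("genotype"):
        doses = set(grp["dose"])
        if doses != {dose, vehicle}:
            raise ValueError(
                f"genotype {genotype!r} is missing a group: has doses {sorted(doses)}"
            )
        mean = grp.groupby("dose")[state].mean()
        contrasts[str(genotype)] = float(mean[dose] - mean[vehicle])
    if not contrasts:
        raise ValueError("no genotype groups present")
    return contrasts, subset


# ---------------------------------------------------------------------------
# ELISA
# ---------------------------------------------------------------------------

def normalize_elisa(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw ELISA readings (pg/ml) to total protein (mg/ml).

    Adds a ``normalized_pg_mg`` column.  Rows with non-positive protein are
    dropped and reported in ``result.attrs["rejected_rows"]``.
    """
    needed = {"region", "abeta_pg_ml", "protein_mg_ml"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"ELISA table is missing columns {sorted(missing)}")
    bad = table["protein_mg_ml"] <= 0
    out = table.loc[~bad].copy()
    out["normalized_pg_mg"] = out["abeta_pg_ml"] / out["protein_mg_ml"]
    out.attrs["rejected_rows"] = table.index[bad].tolist()
    return out


def region_fold_ratios(table: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Fold ratios of group-mean normalized amyloid levels between regions.

    Computed on group means (ratio of means, not mean of ratios).  Requires
    at least two regions with at least two samples each; returns every
    ordered pair.
    """
    if "normalized_pg_mg" not in table.columns:
        table = normalize_elisa(table)
    counts = table.groupby("region")["normalized_pg_mg"].count()
    if len(counts) < 2:
        raise ValueError("fold ratios need at least two regions")
    if (counts < 2).any():
        thin = counts[counts < 2].index.tolist()
        raise ValueError(f"regions with fewer than two samples: {thin}")
    means = table.groupby("region")["normalized_pg_mg"].mean()
    return {
        (a, b): float(means[a] / means[b])
        for a in means.index
        for b in means.index
        if a != b
    }
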