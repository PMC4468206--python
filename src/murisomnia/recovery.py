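"""Planted-effect recovery experiments.

Every packaged fixture plants known effect magnitudes (genotype contrasts
in percent state time, deprivation-window composition, rebound delta
shift, dose responses, region fold ratios).  The functions here run the
full analysis pipeline on freshly simulated data and return the recovered
magnitudes, averaged over replicate master seeds.  They are the package's
end-to-end validation surface: if a recovered value drifts from its
planted value beyond sampling error, some stage of the pipeline is broken.
"""

from __future__ import annotations

import numpy as np

from .pipeline import run_baseline_cohort, run_elisa, run_prazosin, run_tsd
from .synth import load_fixture


def _seeds(seed: int, n: int) -> list[int]:
    """Replicate master seeds: consecutive integers from ``seed``."""
    return [int(seed) + i for i in range(n)]


def genotype_contrasts(seed: int, n_seeds: int = 10, fixture: str = "3mo") -> dict:
    """Tg-minus-NTg percent-time contrasts per phase/state, seed-averaged.

    Simulates the baseline cohort at epoch fidelity (truth hypnograms feed
    the architecture stage directly) and averages the group contrasts over
    ``n_seeds`` independent cohorts.
    """
    per_seed = [run_baseline_cohort(fixture, s)["contrasts"] for s in _seeds(seed, n_seeds)]
    keys = per_seed[0].keys()
    out = {k: float(np.mean([c[k] for c in per_seed])) for k in keys}
    out["n_subjects"] = n_seeds * sum(
        spec["n"] for spec in load_fixture(fixture)["groups"].values()
    )
    return out


def tsd_wake_recovery(seed: int, n_seeds: int = 10, group: str = "Tg",
                      fixture: str = "tsd") -> dict:
    """Mean percent wake scored inside the deprivation window."""
    values = []
    n_subjects = 0
    for s in _seeds(seed, n_seeds):
        eff = run_tsd(fixture, s)["efficacy"]
        sub = eff[eff["group"] == group]
        values.append(sub["W"].mean())
        n_subjects += len(sub)
    return {"wake_pct": float(np.mean(values)), "n_subjects": n_subjects}


def rebound_shift_recovery(seed: int, n_seeds: int = 10, group: str = "NTg",
                           fixture: str = "tsd") -> dict:
    """Mean percent change in NREM delta power, rebound vs baseline."""
    values = []
    n_subjects = 0
    for s in _seeds(seed, n_seeds):
        shifts = run_tsd(fixture, s)["delta_shifts"]
        sub = shifts[shifts["group"] == group]
        values.append(sub["delta_shift_pct"].mean())
        n_subjects += len(sub)
    return {"delta_shift_pct": float(np.mean(values)), "n_subjects": n_subjects}


def prazosin_contrast_recovery(seed: int, dose: float, genotype: str,
                               n_seeds: int = 10, fixture: str = "prazosin") -> dict:
    """Mean NREM percentage-point change (dose minus vehicle)."""
    values = []
    for s in _seeds(seed, n_seeds):
        contrasts = run_prazosin(fixture, s)["nrem_contrasts"]
        values.append(contrasts[dose][genotype])
    fx = load_fixture(fixture)
    n = fx["groups"][genotype][str(int(dose))]["n"] + fx["groups"][genotype]["0"]["n"]
    return {"nrem_points": float(np.mean(values)), "n_subjects": n_seeds * n}


def elisa_fold_recovery(seed: int, n_seeds: int = 20, age: str = "3mo",
                        numerator: str = "prefrontal_cortex",
                        denominator: str = "thalamus",
                        fixture: str = "elisa") -> dict:
    """Mean fold ratio of group-mean normalized amyloid levels."""
    values = []
    n_samples = 0
    for s in _seeds(seed, n_seeds):
        result = run_elisa(fixture, s, age=age)
        values.append(result["folds"][(numerator, denominator)])
        n_samples += int(
            result["table"]["region"].isin([numerator, denominator]).sum()
        )
    return {"fold": float(np.mean(values)), "n_samples": n_samples}


def scorer_recovery(seed: int, n_seeds: int = 10, duration_s: float = 3600.0,
                    fixture: str = "3mo") -> dict:
    """Epoch-label agreement between scored and truth hypnograms on clean
    signal-fidelity records, alternating groups and starting phases."""
    import datetime as dt

    from . import scoring
    from .synth import config_from_group, simulate_hypnogram, synthesize_signals

    fx = load_fixture(fixture)
    groups = list(fx["groups"])
    agreements = []
    for i, s in enumerate(_seeds(seed, n_seeds)):
        label = groups[i % len(groups)]
        config = config_from_group(fx["groups"][label], label, fidelity="signal")
        start = dt.datetime(2015, 1, 1, 12 if (i // 2) % 2 == 0 else 21, 0)
        truth = simulate_hypnogram(config, duration_s, start, seed=s)
        rec = synthesize_signals(truth, config, seed=s + 7919)
        scored = scoring.score_recording(rec)
        agreements.append(float(np.mean(scored.states == truth.states)))
    return {
        "mean_agreement": float(np.mean(agreements)),
        "min_agreement": float(np.min(agreements)),
        "per_record": agreements,
        "n_epochs": int(n_seeds * duration_s / 5.0),
    }
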