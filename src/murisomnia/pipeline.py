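"""End-to-end scenario runs: simulate -> (score) -> spectra -> architecture
-> protocol analysis -> statistics, with TSV outputs and a reproducibility
manifest.

Each scenario has a plain-function runner returning in-memory results, and
:func:`run_pipeline` wraps a runner with file output, per-stage logging and
a manifest (seed, fixture, per-file checksums) so identical config + seed
reproduce identical outputs.  Epoch-level fidelity is the default for
cohort scenarios; signal-level synthesis plus automated scoring is reserved
for scorer validation.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import architecture, protocols, scoring, spectral, stats, synth
from .io import STATES, write_hypnogram

log = logging.getLogger("murisomnia")

_DAY1 = dt.date(2015, 1, 1)

SCENARIOS = ("baseline_cohort", "tsd", "prazosin", "elisa")


@dataclass
class RunConfig:
    scenario: str
    fixture: str
    out_dir: str | Path
    seed: int
    fidelity: str | None = None  # None: fixture/scenario default
    stages: dict = field(default_factory=dict)  # e.g. {"stats": False}

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")


def _start_time(fixture: dict) -> dt.datetime:
    hh, mm = (int(x) for x in fixture.get("start_time", "20:00").split(":"))
    return dt.datetime.combine(_DAY1, dt.time(hh, mm))


def _stage(name: str, **counts) -> None:
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


# ---------------------------------------------------------------------------
# Scenario runners
# ---------------------------------------------------------------------------

def run_baseline_cohort(
    fixture: dict | str,
    seed: int,
    fidelity: str = "epoch",
    score: bool | None = None,
) -> dict:
    """Simulate a baseline cohort and summarize its sleep architecture.

    With epoch fidelity the truth hypnograms feed the architecture stage
    directly (score-bypass); with signal fidelity the raw signals are
    scored by the rule-based classifier first.
    """
    if isinstance(fixture, str):
        fixture = synth.load_fixture(fixture)
    start = _start_time(fixture)
    duration_s = float(fixture.get("duration_h", 24)) * 3600.0
    design = [
        (label, spec["n"], synth.config_from_group(spec, label, fidelity=fidelity,
                                                   animal_cv=fixture.get("animal_cv", 0.10)))
        for label, spec in fixture["groups"].items()
    ]
    animals = synth.simulate_cohort(
        design, seed=seed, duration_s=duration_s, start_time=start,
        group_effects=fixture.get("planted_contrasts", {}),
    )
    _stage("simulate", animals=len(animals), epochs=sum(len(a.hypnogram) for a in animals))

    score = (fidelity == "signal") if score is None else score
    rows = []
    for animal in animals:
        hyp = animal.hypnogram
        if score:
            hyp = scoring.score_recording(animal.recording)
        summary = architecture.summarize(hyp)
        tidy = summary.table.reset_index()
        tidy.insert(0, "group", animal.group)
        tidy.insert(0, "subject", animal.subject_id)
        rows.append(tidy)
    arch = pd.concat(rows, ignore_index=True)
    _stage("architecture", rows=len(arch))

    # group contrasts in percent time, per phase x state
    wide = arch.pivot_table(index=["subject", "group"], columns=["phase", "state"],
                            values="percent_time")
    group_means = wide.groupby("group").mean()
    contrasts = {}
    if {"Tg", "NTg"} <= set(group_means.index):
        diff = group_means.loc["Tg"] - group_means.loc["NTg"]
        contrasts = {f"{ph}_{st}": float(diff[(ph, st)]) for ph, st in diff.index}

    anovas = {}
    for (ph, st) in [("dark", "W"), ("dark", "NR"), ("light", "W"), ("light", "NR")]:
        tbl = arch[(arch["phase"] == ph) & (arch["state"] == st)]
        x = tbl[tbl["group"] == "NTg"]["percent_time"]
        y = tbl[tbl["group"] == "Tg"]["percent_time"]
        if len(x) >= 2 and len(y) >= 2:
            anovas[f"{ph}_{st}"] = stats.t_unpaired(y, x)
    _stage("stats", tests=len(anovas))
    return {"animals": animals, "architecture": arch, "contrasts": contrasts,
            "group_means": group_means, "tests": anovas,
            "planted": fixture.get("planted_contrasts", {})}


def run_tsd(fixture: dict | str, seed: int) -> dict:
    """Simulate the deprivation protocol and quantify efficacy and rebound."""
    if isinstance(fixture, str):
        fixture = synth.load_fixture(fixture)
    start = _start_time(fixture)
    duration_s = float(fixture.get("duration_h", 48)) * 3600.0
    design = protocols.DeprivationDesign.standard(_DAY1)
    children = np.random.SeedSequence(seed).spawn(
        sum(spec["n"] for spec in fixture["groups"].values())
    )
    epoch_s = 5.0
    rows, shift_rows, duration_rows = [], [], []
    k = 0
    for label, spec in fixture["groups"].items():
        config = synth.config_from_group(spec, label,
                                         animal_cv=fixture.get("animal_cv", 0.10))
        rebound = spec.get("rebound", {})
        for i in range(spec["n"]):
            rng = np.random.default_rng(children[k])
            k += 1
            subject = f"{label}_{i + 1:02d}"
            hyp = synth.simulate_tsd(
                config,
                tsd_window=design.tsd_window,
                residual_sleep=spec.get("residual_sleep", {}),
                duration_s=duration_s,
                start_time=start,
                rebound_window=design.rebound_window,
                rebound_fractions=rebound.get("state_fractions"),
                seed=rng,
                subject_id=subject,
            )
            eff = protocols.tsd_efficacy(hyp, design.tsd_window)
            rows.append({"subject": subject, "group": label, **eff})

            # per-epoch band fractions with the delta boost confined to the
            # rebound window, then window-averaged NREM spectra
            factor = np.ones(len(hyp))
            lo = int((design.rebound_window[0] - start).total_seconds() / epoch_s)
            hi = int((design.rebound_window[1] - start).total_seconds() / epoch_s)
            factor[lo:hi] = float(rebound.get("delta_factor", 1.0))
            bands = synth.generate_band_fractions(hyp, config, seed=rng,
                                                  delta_factor=factor)
            b_lo = int((design.baseline_window[0] - start).total_seconds() / epoch_s)
            b_hi = int((design.baseline_window[1] - start).total_seconds() / epoch_s)

            def nrem_spectrum(sl: slice):
                mask = hyp.states[sl] == "NR"
                sub = bands.iloc[sl].loc[np.asarray(mask)]
                mean = sub.mean(axis=0).to_dict()
                return spectral.spectrum_from_band_fractions(
                    {k2: v for k2, v in mean.items() if k2 != "rest"}
                )

            shift = protocols.rebound_delta_shift(
                nrem_spectrum(slice(b_lo, b_hi)), nrem_spectrum(slice(lo, hi))
            )
            shift_rows.append({"subject": subject, "group": label,
                               "delta_shift_pct": shift})

            dur = protocols.rebound_duration_change(hyp, design)
            for st in STATES:
                duration_rows.append(
                    {"subject": subject, "group": label, "state": st,
                     "baseline": dur.loc[st, "baseline"],
                     "rebound": dur.loc[st, "rebound"]}
                )
    efficacy = pd.DataFrame(rows)
    shifts = pd.DataFrame(shift_rows)
    durations = pd.DataFrame(duration_rows)
    _stage("tsd", animals=len(efficacy))

    # mixed ANOVA per state: genotype (between) x time period (within)
    mixed = {}
    for st in STATES:
        sub = durations[durations["state"] == st]
        long = sub.melt(id_vars=["subject", "group"], value_vars=["baseline", "rebound"],
                        var_name="period", value_name="percent")
        mixed[st] = stats.anova_mixed(long, between="group", within="period",
                                      subject="subject", value="percent")
    _stage("stats", tests=len(mixed))
    return {"efficacy": efficacy, "delta_shifts": shifts, "durations": durations,
            "mixed_anova": mixed, "design": design,
            "planted": fixture.get("planted", {})}


def run_prazosin(fixture: dict | str, seed: int) -> dict:
    """Simulate post-injection windows and quantify the dose response."""
    if isinstance(fixture, str):
        fixture = synth.load_fixture(fixture)
    hh, mm = (int(x) for x in fixture.get("injection_time", "10:00").split(":"))
    injection = dt.datetime.combine(_DAY1, dt.time(hh, mm))
    window_h = float(fixture.get("window_h", 2))
    duration_s = window_h * 3600.0
    total_n = sum(spec["n"] for doses in fixture["groups"].values()
                  for spec in doses.values())
    children = np.random.SeedSequence(seed).spawn(total_n)
    rows = []
    k = 0
    for genotype, doses in fixture["groups"].items():
        for dose_label, spec in doses.items():
            dose = float(dose_label)
            config = synth.config_from_group(spec, f"{genotype}_{dose_label}",
                                             animal_cv=fixture.get("animal_cv", 0.10))
            record = protocols.TreatmentRecord(dose=dose, injection_time=injection,
                                               analysis_window_h=window_h)
            for i in range(spec["n"]):
                rng = np.random.default_rng(children[k])
                k += 1
                targets = synth._jitter_fractions(config, rng)
                hyp = synth.simulate_hypnogram(
                    config, duration_s, injection, seed=rng,
                    subject_id=f"{genotype}_{dose_label}_{i + 1:02d}",
                    fractions_override=targets,
                )
                pct = protocols.treatment_window_summary(hyp, record)
                rows.append({"subject": hyp.subject_id, "genotype": genotype,
                             "dose": dose, **pct})
    summaries = pd.DataFrame(rows)
    _stage("treatment", animals=len(summaries))

    contrasts, anovas = {}, {}
    for dose in sorted(set(summaries["dose"]) - {0.0}):
        diff, subset = protocols.dose_contrast(summaries, dose=dose, vehicle=0.0)
        contrasts[dose] = diff
        long = subset.rename(columns={"NR": "value"})
        anovas[dose] = stats.anova_two_way_between(long, factor_a="genotype",
                                                   factor_b="dose", value="value")
    _stage("stats", doses=len(contrasts))
    return {"summaries": summaries, "nrem_contrasts": contrasts, "anovas": anovas,
            "planted": fixture.get("planted", {})}


def run_elisa(fixture: dict | str, seed: int, age: str = "3mo") -> dict:
    """Simulate one age's ELISA table, normalize, and compare regions."""
    if isinstance(fixture, str):
        fixture = synth.load_fixture(fixture)
    spec = fixture["ages"][age]
    table = synth.simulate_elisa(
        region_means=spec["region_means_pg_mg"],
        cv=float(fixture.get("cv", 0.2)),
        protein_mg_ml=float(fixture.get("protein_mg_ml", 3.0)),
        n=int(spec["n"]),
        seed=seed,
    )
    normalized = protocols.normalize_elisa(table)
    folds = protocols.region_fold_ratios(normalized)
    _stage("elisa", samples=len(normalized), regions=normalized["region"].nunique())

    # one-way within-subject ANOVA across regions (samples paired by animal)
    normalized = normalized.copy()
    normalized["animal"] = normalized["sample"].str.rsplit("_", n=1).str[-1]
    anova = stats.anova_one_way_within(normalized, subject="animal", level="region",
                                       value="normalized_pg_mg")
    means = normalized.groupby("region")["normalized_pg_mg"].agg(["mean", "count"])
    mse = float(
        normalized.groupby("region")["normalized_pg_mg"]
        .transform(lambda v: v - v.mean()).pow(2).sum() / anova.df_den
    )
    anova.followup = stats.tukey_hsd(
        means["mean"].to_dict(), means["count"].to_dict(), mse, anova.df_den
    )
    _stage("stats", tests=1)
    return {"table": normalized, "folds": folds, "anova": anova,
            "planted": fixture.get("planted", {})}


_RUNNERS = {
    "baseline_cohort": run_baseline_cohort,
    "tsd": run_tsd,
    "prazosin": run_prazosin,
    "elisa": run_elisa,
}


# ---------------------------------------------------------------------------
# File-level orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Run a scenario end to end and write TSV outputs plus a manifest.

    Idempotent: identical config and seed produce identical outputs and
    manifest checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixture = synth.load_fixture(config.fixture)
    if fixture.get("scenario") != config.scenario:
        raise ValueError(
            f"fixture {config.fixture!r} encodes scenario {fixture.get('scenario')!r}, "
            f"not {config.scenario!r}"
        )
    kwargs = {}
    if config.scenario == "baseline_cohort" and config.fidelity:
        kwargs["fidelity"] = config.fidelity
    result = _RUNNERS[config.scenario](fixture, config.seed, **kwargs)

    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        _write_tsv(df, path)
        written.append(path)

    stages = {"tables": True, "hypnograms": False, "report": True}
    stages.update(config.stages)

    if config.scenario == "baseline_cohort":
        if stages["tables"]:
            emit("architecture.tsv", result["architecture"])
        if stages["hypnograms"]:
            for animal in result["animals"]:
                path = out / f"hypnogram_{animal.subject_id}.csv"
                write_hypnogram(animal.hypnogram, path)
                written.append(path)
        truth = {"contrasts": result["contrasts"], "planted": result["planted"]}
        (out / "planted_truth.json").write_text(json.dumps(truth, indent=2))
        written.append(out / "planted_truth.json")
    elif config.scenario == "tsd":
        if stages["tables"]:
            emit("tsd_efficacy.tsv", result["efficacy"])
            emit("delta_shifts.tsv", result["delta_shifts"])
            emit("durations.tsv", result["durations"])
    elif config.scenario == "prazosin":
        if stages["tables"]:
            emit("treatment_summaries.tsv", result["summaries"])
    elif config.scenario == "elisa":
        if stages["tables"]:
            emit("elisa.tsv", result["table"])
            folds = pd.DataFrame(
                [{"numerator": a, "denominator": b, "fold": f}
                 for (a, b), f in result["folds"].items()]
            )
            emit("fold_ratios.tsv", folds)

    if stages.get("report", True):
        report = make_report(result, config.scenario)
        for name, df in report.items():
            emit(f"report_{name}.tsv", df.reset_index())

    manifest = {
        "scenario": config.scenario,
        "fixture": str(config.fixture),
        "seed": config.seed,
        "fidelity": config.fidelity,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _stage("manifest", files=len(written))
    return manifest


def make_report(result: dict, scenario: str) -> dict[str, pd.DataFrame]:
    """Per-group mean +/- SEM summary tables in the study's layouts.

    Single-subject groups flag the SEM as undefined (NaN).
    """
    def mean_sem(df: pd.DataFrame, by: list[str], value: str) -> pd.DataFrame:
        g = df.groupby(by)[value]
        out = g.agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v))
                    if len(v) > 1 else np.nan, n="count")
        return out

    if scenario == "baseline_cohort":
        arch = result["architecture"]
        return {
            "percent_time": mean_sem(arch, ["group", "phase", "state"], "percent_time"),
            "episodes": mean_sem(arch, ["group", "phase", "state"], "mean_episode_s"),
            "transitions": mean_sem(arch, ["group", "phase", "state"], "n_transitions"),
        }
    if scenario == "tsd":
        long = result["durations"].melt(
            id_vars=["subject", "group", "state"], value_vars=["baseline", "rebound"],
            var_name="period", value_name="percent")
        return {
            "efficacy": mean_sem(result["efficacy"], ["group"], "W"),
            "delta_shift": mean_sem(result["delta_shifts"], ["group"], "delta_shift_pct"),
            "durations": mean_sem(long, ["group", "state", "period"], "percent"),
        }
    if scenario == "prazosin":
        summaries = result["summaries"].melt(
            id_vars=["subject", "genotype", "dose"], value_vars=list(STATES),
            var_name="state", value_name="percent")
        return {"treatment": mean_sem(summaries, ["genotype", "dose", "state"], "percent")}
    if scenario == "elisa":
        return {"regions": mean_sem(result["table"], ["region"], "normalized_pg_mg")}
    raise ValueError(f"unknown scenario {scenario!r}")
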