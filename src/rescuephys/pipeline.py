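"""End-to-end orchestration: simulate -> segment -> detect -> spectral -> stats.

A run is driven by a plain-text config (YAML or JSON) and produces a JSON
report whose every number is traceable to the logged stage parameters and
seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from rescuephys import __version__, behavior, io, spectral
from rescuephys.core import ContractError, Recording
from rescuephys.iis import detect_spikes, reject_artifacts, spike_rate_by_state
from rescuephys.states import segment_states

DEFAULT_STAGE_PARAMS: dict = {
    "segment": {"emg_window_s": 1.0, "quiet_ratio": 0.5, "min_bout_s": 10.0},
    "detect": {"threshold_mV": 1.0, "refractory_s": 0.2},
    "reject": {"sync_window_s": 0.01, "sync_min_channels": 2, "amp_cap_mV": 10.0},
    "spectral": {
        "window_min": 10.0,
        "n_cycles": 6.0,
        "n_boot": 2000,
        "n_shuffles": 5000,
        "theta_band": [6.0, 12.0],
    },
}


@dataclass
class RunConfig:
    """Parsed run configuration: manifest, stage parameters, seed, output."""

    manifest: list = field(default_factory=list)
    cohort_file: Optional[str] = None
    plan: list = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: Optional[str] = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        cfg = cls(
            manifest=raw.get("manifest", []),
            cohort_file=raw.get("cohort_file"),
            plan=raw.get("plan", []),
            params=raw.get("params", {}),
            seed=int(raw.get("seed", 0)),
            out_dir=raw.get("out_dir"),
        )
        for entry in cfg.manifest:
            if "file" in entry and not Path(entry["file"]).exists():
                raise ContractError(f"manifest file missing: {entry['file']}")
        if cfg.cohort_file and not Path(cfg.cohort_file).exists():
            raise ContractError(f"cohort file missing: {cfg.cohort_file}")
        return cfg

    def stage_params(self, stage: str) -> dict:
        merged = dict(DEFAULT_STAGE_PARAMS.get(stage, {}))
        merged.update(self.params.get(stage, {}))
        return merged


def _provenance(config: RunConfig) -> dict:
    return {
        "package_version": __version__,
        "seed": config.seed,
        "stage_params": {
            stage: config.stage_params(stage) for stage in DEFAULT_STAGE_PARAMS
        },
    }


def _session_metrics(rec: Recording, config: RunConfig) -> dict:
    states = segment_states(rec, **config.stage_params("segment"))
    events = detect_spikes(rec, **config.stage_params("detect"))
    events = reject_artifacts(events, rec, **config.stage_params("reject"))
    rates = spike_rate_by_state(events, states)
    return {
        "wake_rate": rates.wake_rate,
        "sleep_rate": rates.sleep_rate,
        "wake_time_s": rates.wake_time_s,
        "sleep_time_s": rates.sleep_time_s,
        "n_events": len(events.accepted),
    }


def run_ephys_study(config: RunConfig) -> dict:
    """Phase I vs Phase II electrophysiology study.

    Produces per-animal state-resolved spike rates per phase, a mixed
    repeated-measures ANOVA on wake rates (genotype x phase), a paired
    wake-vs-sleep t test in Phase I mutants, and the theta-band amplitude
    change with bootstrap CI and permutation p.
    """
    report: dict = {"provenance": _provenance(config), "errors": []}
    if not config.manifest:
        report["errors"].append("empty manifest; nothing to analyze")
        return report

    sp = config.stage_params("spectral")

    by_animal: dict[str, dict[str, list[dict]]] = {}
    specs: dict[str, dict[str, list]] = {"I": {}, "II": {}}
    genotypes: dict[str, str] = {}
    for entry in config.manifest:
        rec = io.read_recording(entry["file"])
        animal = entry.get("animal_id", rec.meta.get("animal_id", "unknown"))
        phase = entry.get("phase", rec.meta.get("phase", "I"))
        genotypes[animal] = entry.get("genotype", rec.meta.get("genotype", "?"))
        metrics = _session_metrics(rec, config)
        by_animal.setdefault(animal, {}).setdefault(phase, []).append(metrics)
        win = spectral.analysis_window(rec, minutes=sp["window_min"])
        spec = spectral.morlet_amplitude(
            win.channel("hlfp"), win.fs, n_cycles=sp["n_cycles"]
        )
        specs.setdefault(phase, {}).setdefault(animal, []).append(spec)

    paired = sorted(a for a in by_animal if {"I", "II"} <= set(by_animal[a]))
    unpaired = sorted(set(by_animal) - set(paired))
    if unpaired:
        warnings.warn(f"excluding unpaired animals: {unpaired}", stacklevel=2)
        report["errors"].append(f"unpaired animals excluded: {unpaired}")
    if not paired:
        report["errors"].append("no animal has both phases")
        return report

    def mean_of(animal: str, phase: str, key: str) -> Optional[float]:
        vals = [
            m[key] for m in by_animal[animal][phase] if m[key] is not None
        ]
        return float(np.mean(vals)) if vals else None

    rates_rows = []
    for a in paired:
        for phase in ("I", "II"):
            rates_rows.append(
                {
                    "animal_id": a,
                    "genotype": genotypes[a],
                    "phase": phase,
                    "wake_rate": mean_of(a, phase, "wake_rate"),
                    "sleep_rate": mean_of(a, phase, "sleep_rate"),
                }
            )
    rates_df = pd.DataFrame(rates_rows)
    report["per_animal_rates"] = rates_rows

    # mixed RM ANOVA on wake rates: genotype (between) x phase (within)
    try:
        long = rates_df.rename(columns={"wake_rate": "value"})[
            ["animal_id", "genotype", "phase", "value"]
        ].dropna()
        long["endpoint"] = "wake_rate"
        long["tmx"] = long["phase"]
        res = behavior.mixed_rm_anova(long, "wake_rate", within="tmx")
        report["wake_rate_mixed_anova"] = [r.to_dict() for r in res]
    except Exception as exc:  # report, don't abort the run
        report["errors"].append(f"mixed ANOVA failed: {exc}")

    # paired wake-vs-sleep t in mutant animals, Phase I
    mutants = [a for a in paired if genotypes[a] in ("+/ls", "+/-")]
    wake = [mean_of(a, "I", "wake_rate") for a in mutants]
    sleep = [mean_of(a, "I", "sleep_rate") for a in mutants]
    ok = [
        (w, s) for w, s in zip(wake, sleep) if w is not None and s is not None
    ]
    if len(ok) >= 2:
        w, s = zip(*ok)
        res = behavior.group_compare(list(w), list(s), test="paired_t")
        report["mutant_wake_vs_sleep_paired_t"] = res.to_dict()
    else:
        report["errors"].append(
            "not enough mutant animals with both states for the paired t test"
        )

    # theta amplitude change with CI + permutation p
    try:
        change = spectral.normalized_amplitude_change(specs["I"], specs["II"])
        change = spectral.bootstrap_ci(
            change, n_boot=sp["n_boot"], seed=config.seed
        )
        perm = spectral.band_permutation_test(
            change,
            band=tuple(sp["theta_band"]),
            n_shuffles=sp["n_shuffles"],
            seed=config.seed,
        )
        report["amplitude_change"] = {
            "freqs_hz": change.freqs_hz.tolist(),
            "grand_mean": change.grand_mean.tolist(),
            "ci_low": change.ci_low.tolist(),
            "ci_high": change.ci_high.tolist(),
            "theta_permutation_p": perm.p,
            "theta_observed_change": perm.observed,
            "n_animals": len(change.animals),
        }
    except ContractError as exc:
        report["errors"].append(f"spectral stage failed: {exc}")

    _maybe_write(report, config, "ephys_report.json")
    return report


def run_behavior_study(config: RunConfig) -> dict:
    """Cohort-table statistics driven by an analysis plan."""
    report: dict = {"provenance": _provenance(config), "errors": [], "analyses": []}
    if not config.cohort_file:
        report["errors"].append("no cohort_file configured")
        return report
    table = io.read_cohort(config.cohort_file)
    for item in config.plan:
        design = item.get("design")
        endpoint = item.get("endpoint")
        entry = {"design": design, "endpoint": endpoint}
        try:
            if design == "two_factor_anova":
                factors = tuple(item.get("factors", ("cre", "genotype")))
                res = behavior.two_factor_anova(table, endpoint, factors=factors)
                entry["results"] = [r.to_dict() for r in res]
            elif design == "manova":
                res = behavior.manova(
                    table,
                    endpoints=item.get("endpoints", []),
                    factors=tuple(item.get("factors", ("cre", "genotype"))),
                )
                entry["results"] = [r.to_dict() for r in res]
            elif design == "mixed_rm_anova":
                res = behavior.mixed_rm_anova(
                    table,
                    endpoint,
                    between=item.get("between", "genotype"),
                    within=item.get("within", "tmx"),
                )
                entry["results"] = [r.to_dict() for r in res]
            elif design == "bonferroni_pairwise":
                sub = table.copy()
                sub["group"] = sub["cre"] + ";" + sub["genotype"]
                res = behavior.bonferroni_pairwise(sub, endpoint)
                entry["results"] = [r.to_dict() for r in res]
            elif design == "group_compare":
                factor = item.get("factor", "genotype")
                levels = item.get("levels")
                sub = table[table["endpoint"] == endpoint]
                if levels is None:
                    levels = sorted(sub[factor].unique())
                a = sub.loc[sub[factor] == levels[0], "value"].to_numpy()
                b = sub.loc[sub[factor] == levels[1], "value"].to_numpy()
                res = behavior.group_compare(a, b, test=item.get("test", "unpaired_t"))
                res.effect_size = behavior.cohens_d(a, b)
                entry["results"] = [res.to_dict()]
            else:
                raise ContractError(f"unknown design {design!r}")
        except ContractError as exc:
            entry["error"] = str(exc)
            report["errors"].append(f"{design}/{endpoint}: {exc}")
        report["analyses"].append(entry)
    _maybe_write(report, config, "behavior_report.json")
    return report


def _maybe_write(report: dict, config: RunConfig, name: str) -> None:
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / name).write_text(json.dumps(report, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
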