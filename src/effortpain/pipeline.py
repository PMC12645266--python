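"""End-to-end pipeline orchestration: simulate -> fit -> compare -> validate -> stats.

A single YAML-configurable entry point reproducing the full analysis chain
on either simulated or user-supplied data.  Every random stage consumes a
sub-seed derived (and logged) from the one top-level seed, so a config
reruns bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import sys
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavioral_stats import bf_category, jzs_paired_bf, summarize_behavior
from .inference.fit import SamplerConfig, fit_model, save_fit
from .io import read_dataset, write_dataset
from .model_comparison import compare_models
from .synthetic_data import AgentPopulationConfig, sample_population, simulate_dataset
from .task_design import generate_schedule, write_schedule_csv
from .validation import parameter_recovery, posterior_predictive
from .value_models import ModelSpec

__all__ = ["RunConfig", "run_pipeline", "behavioral_tests"]


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    n_per_recipient: int = 75
    population: dict = dataclasses.field(default_factory=dict)
    models: list[str] = dataclasses.field(default_factory=lambda: ["parabolic_2k1b"])
    sampler: dict = dataclasses.field(default_factory=dict)
    data_csv: str | None = None          # fit existing data instead of simulating
    ppc_reps: int = 100
    run_recovery: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        pathlib.Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str) -> None:
    print(f"[effortpain] {msg}", file=sys.stderr)


def behavioral_tests(per_subject: pd.DataFrame) -> dict:
    """Self-vs-other paired default-prior Bayes factors on subject summaries."""
    wide = per_subject.pivot(index="subject_id", columns="recipient")
    out = {}
    for metric in ("work_choice_rate", "mean_rt_s", "mean_force_auc", "success_rate"):
        pair = wide[metric].dropna()
        if len(pair) < 3 or pair["self"].std(ddof=1) + pair["other"].std(ddof=1) == 0:
            continue
        bf01 = jzs_paired_bf(pair["self"], pair["other"])
        out[metric] = {
            "n_pairs": int(len(pair)),
            "mean_self": float(pair["self"].mean()),
            "mean_other": float(pair["other"].mean()),
            "bf01": bf01,
            "evidence": bf_category(bf01),
        }
    return out


def run_pipeline(config: RunConfig, out_dir) -> pathlib.Path:
    """Execute the full chain and write all artifacts under ``out_dir``."""
    t_start = time.time()
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(seq.generate_state(1)[0])
        for name, seq in zip(
            ("schedule", "population", "simulate", "fits", "ppc", "recovery"),
            root.spawn(6),
        )
    }
    seeds_used: dict = dict(stage_seeds)

    for name in config.models:
        ModelSpec.from_name(name)  # fail fast on typos

    _log(f"schedule: {2 * config.n_per_recipient} trials")
    schedule = generate_schedule(config.n_per_recipient, seed=stage_seeds["schedule"])
    write_schedule_csv(schedule, out / "schedule.csv")

    if config.data_csv:
        _log(f"loading dataset from {config.data_csv}")
        data = read_dataset(config.data_csv)
        truth = None
    else:
        pop_kwargs = dict(config.population)
        model_name = pop_kwargs.pop("model", config.models[0])
        pop = AgentPopulationConfig(
            model=ModelSpec.from_name(model_name),
            seed=stage_seeds["population"],
            **pop_kwargs,
        )
        agents = sample_population(pop)
        _log(f"simulating {pop.n_subjects} subjects under {pop.model.name}")
        data = simulate_dataset(agents, schedule, pop, seed=stage_seeds["simulate"])
        truth = pd.DataFrame(
            [dataclasses.asdict(a) | {"subject_id": i + 1} for i, a in enumerate(agents)]
        )
        truth.to_csv(out / "truth.csv", index=False)
    write_dataset(data, out / "data.csv")

    sampler_kwargs = dict(config.sampler)
    fits = []
    fit_seed_root = np.random.SeedSequence(stage_seeds["fits"])
    for name, seq in zip(config.models, fit_seed_root.spawn(len(config.models))):
        seed = int(seq.generate_state(1)[0])
        seeds_used[f"fit:{name}"] = seed
        _log(f"fitting {name}")
        fit = fit_model(
            data, ModelSpec.from_name(name),
            sampler=SamplerConfig(seed=seed, **sampler_kwargs),
        )
        if not fit.converged:
            _log(f"  warning: {name} max R-hat {fit.max_rhat:.3f} >= 1.01")
        save_fit(fit, out / "fits" / name)
        fits.append(fit)

    if len(fits) > 1:
        _log("comparing models")
        comparison = compare_models(fits)
        (out / "comparison.json").write_text(json.dumps(comparison.to_dict(), indent=2))
        winner_name = comparison.table.loc[0, "model"]
    else:
        winner_name = fits[0].model.name
    winner = next(f for f in fits if f.model.name == winner_name)

    _log(f"posterior predictive check on {winner_name}")
    ppc = posterior_predictive(
        winner, schedule, n_reps=config.ppc_reps, seed=stage_seeds["ppc"]
    )
    ppc.to_csv(out / "ppc.csv", index=False)

    if config.run_recovery:
        _log(f"parameter recovery for {winner_name}")
        report, _ = parameter_recovery(
            winner.model, winner, seed=stage_seeds["recovery"],
            sampler=SamplerConfig(seed=stage_seeds["recovery"], **sampler_kwargs),
            schedule=schedule,
        )
        (out / "recovery.json").write_text(json.dumps(report.to_dict(), indent=2))

    _log("behavioral summaries")
    per_subject, group, flags = summarize_behavior(data)
    per_subject.to_csv(out / "behavior_per_subject.csv", index=False)
    stats_payload = {
        "group": {
            f"{metric}_{stat}": {rec: _float_or_none(group.loc[rec, (metric, stat)])
                                 for rec in group.index}
            for metric, stat in group.columns
        },
        "paired_tests": behavioral_tests(per_subject),
        "flags": flags,
    }
    (out / "stats.json").write_text(json.dumps(stats_payload, indent=2))

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": dataclasses.asdict(config),
        "seeds": seeds_used,
        "winner": winner_name,
        "converged": {f.model.name: f.converged for f in fits},
        "max_rhat": {f.model.name: f.max_rhat for f in fits},
        "artifact_sha256": {
            p.name: _sha256(p) for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json"))
            if p.name != "manifest.json"
        },
        "elapsed_s": round(time.time() - t_start, 1),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _log(f"done in {manifest['elapsed_s']}s -> {out}")
    return out


def _float_or_none(v):
    return None if pd.isna(v) else float(v)
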