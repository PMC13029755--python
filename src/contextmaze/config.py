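"""Run configuration, experiment driver and result serialisation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import AgentConfig, make_agent
from .maze import MazeSpec, build_cued_tmaze, build_sequence_task
from .protocols import (
    ExperimentLog,
    Schedule,
    default_schedule,
    metric_block_switch_attempts,
    metric_random_percent_correct,
    run_schedule,
)

__all__ = ["RunConfig", "run_experiment", "sweep", "run_replicates"]


@dataclass
class RunConfig:
    """One experimental condition.

    Defaults reproduce the published hyperparameters and training regimen;
    any override is recorded verbatim in the run manifest.
    """

    task: str = "cued_tmaze"
    mode: str = "FI"
    stem_length: int | None = None
    n_distractors: int = 0
    cue_scale: float | None = None
    n_agents: int = 10
    seed: int = 0
    step_cap: int = 1000
    record_steps: bool = False
    last_k_switches: int = 10
    last_n_random: int = 100
    agent_overrides: dict = field(default_factory=dict)
    output_dir: str | None = None

    def build_spec(self) -> MazeSpec:
        if self.task == "cued_tmaze":
            return build_cued_tmaze(
                stem_length=self.stem_length or 3,
                n_distractors=self.n_distractors,
                cue_scale=self.cue_scale or 4.0,
            )
        return build_sequence_task(self.task, stem_length=self.stem_length or 4)

    def build_agent_config(self, seed: int) -> AgentConfig:
        return AgentConfig.for_task(self.task, mode=self.mode, seed=seed, **self.agent_overrides)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        bad = set(doc) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**doc)


def run_replicates(cfg: RunConfig, record_steps: bool | None = None) -> list[ExperimentLog]:
    """Run ``n_agents`` replicates with seeds seed+0..n-1; returns their logs."""
    spec = cfg.build_spec()
    schedule = default_schedule(cfg.task, spec)
    record = cfg.record_steps if record_steps is None else record_steps
    logs = []
    for i in range(cfg.n_agents):
        agent = make_agent(spec, cfg.build_agent_config(cfg.seed + i))
        log = run_schedule(agent, spec, schedule, seed=cfg.seed + i,
                           step_cap=cfg.step_cap, record_steps=record)
        log.config["agent_seed"] = cfg.seed + i
        log.config["agent"] = agent  # retained for map-level analyses
        logs.append(log)
    return logs


def summarise(cfg: RunConfig, logs: list[ExperimentLog]) -> dict:
    pct = [metric_random_percent_correct(lg, cfg.last_n_random) for lg in logs]
    att = [metric_block_switch_attempts(lg, cfg.last_k_switches) for lg in logs]
    capped = [float(lg.trials["capped"].mean()) for lg in logs]
    return {
        "random_percent_correct_mean": float(np.mean(pct)),
        "random_percent_correct_per_agent": pct,
        "switch_attempts_mean": float(np.mean(att)),
        "switch_attempts_per_agent": att,
        "capped_trial_fraction": float(np.mean(capped)),
    }


def run_experiment(cfg: RunConfig) -> Path:
    """Run one condition; write trials.csv, metrics.json and the manifest.

    The per-step event log is opt-in (``record_steps``) because it dominates
    disk usage; when enabled it is written as steps.csv per replicate.
    """
    out = Path(cfg.output_dir or f"runs/{cfg.task}_{cfg.mode}_seed{cfg.seed}")
    out.mkdir(parents=True, exist_ok=True)
    logs = run_replicates(cfg)
    trials = pd.concat(
        [lg.trials.assign(agent_seed=lg.config["agent_seed"]) for lg in logs],
        ignore_index=True,
    )
    trials.to_csv(out / "trials.csv", index=False)
    if cfg.record_steps:
        for lg in logs:
            lg.steps.to_csv(out / f"steps_seed{lg.config['agent_seed']}.csv", index=False)
    metrics = summarise(cfg, logs)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    manifest = {k: v for k, v in asdict(cfg).items()}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out


def sweep(cfg: RunConfig, axis: str, values: list) -> pd.DataFrame:
    """Run one condition per value of ``axis``; long-format summary table."""
    if axis not in ("distractors", "stem_length"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    rows = []
    if not values:
        import warnings

        warnings.warn("empty sweep value list")
    for v in values:
        c = RunConfig(**{**asdict(cfg), "output_dir": None})
        if axis == "distractors":
            c.n_distractors = int(v)
        else:
            c.stem_length = int(v)
        try:
            logs = run_replicates(c)
            pct = [metric_random_percent_correct(lg, c.last_n_random) for lg in logs]
            att = [metric_block_switch_attempts(lg, c.last_k_switches) for lg in logs]
            for lg, p, a in zip(logs, pct, att):
                seed = lg.config["agent_seed"]
                rows.append((axis, v, cfg.mode, seed, "random_percent_correct", p))
                rows.append((axis, v, cfg.mode, seed, "switch_attempts", a))
        except Exception as exc:  # keep sweeping on per-condition failure
            rows.append((axis, v, cfg.mode, -1, "error", float("nan")))
    return pd.DataFrame(rows, columns=["axis", "value", "mode", "agent_seed", "metric", "result"])
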