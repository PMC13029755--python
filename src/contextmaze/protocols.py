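"""Training regimens and behavioural metrics.

A schedule is an ordered list of phases (blocked, probabilistic-blocked or
random trial-type presentation). Within every trial the agent is allowed as
many attempts as it needs — each arm-end visit counts one attempt; a wrong
end teleports it back to the start — and the per-trial attempt count is the
reversal-speed currency of all block-switch metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maze import MazeSpec

__all__ = [
    "Phase",
    "Schedule",
    "TrialResult",
    "ExperimentLog",
    "default_schedule",
    "run_trial",
    "run_schedule",
    "metric_block_switch_attempts",
    "metric_random_percent_correct",
]


@dataclass(frozen=True)
class Phase:
    """One schedule phase.

    ``kind`` is "blocks", "probabilistic_blocks" or "random". Blocked phases
    rotate round-robin over ``trial_type_pool``; probabilistic blocks flip
    each trial to a uniformly chosen other type with ``off_type_probability``;
    random phases sample the pool uniformly. ``fusion`` marks whether joint
    inference may be active during the phase (further restricted by the
    schedule's global fusion window).
    """

    kind: str
    n_blocks: int
    block_length: int
    trial_type_pool: tuple[str, ...]
    off_type_probability: float = 0.0
    fusion: bool = False

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.block_length


@dataclass(frozen=True)
class Schedule:
    """Ordered phases plus an optional global fusion window (trial indices)."""

    phases: tuple[Phase, ...]
    fusion_window: tuple[int, int] | None = None

    @property
    def n_trials(self) -> int:
        return sum(p.n_trials for p in self.phases)

    def fusion_active(self, trial_idx: int, phase: Phase) -> bool:
        if not phase.fusion:
            return False
        if self.fusion_window is None:
            return True
        lo, hi = self.fusion_window
        return lo <= trial_idx < hi

    def trial_sequence(self, rng: np.random.Generator) -> list[tuple[int, int, str, bool]]:
        """Materialise (phase_idx, block_idx, trial_type, fusion) per trial."""
        seq: list[tuple[int, int, str, bool]] = []
        t = 0
        for pi, phase in enumerate(self.phases):
            pool = phase.trial_type_pool
            for b in range(phase.n_blocks):
                for _ in range(phase.block_length):
                    if phase.kind == "random":
                        tt = pool[rng.integers(len(pool))]
                    else:
                        tt = pool[b % len(pool)]
                        if phase.kind == "probabilistic_blocks" and phase.off_type_probability > 0:
                            if rng.random() < phase.off_type_probability:
                                others = [x for x in pool if x != tt]
                                tt = others[rng.integers(len(others))]
                    seq.append((pi, b, tt, self.fusion_active(t, phase)))
                    t += 1
        return seq


def default_schedule(task: str, spec: MazeSpec | None = None) -> Schedule:
    """The published training regimen for each task.

    cued T-maze: 20 alternating blocks of 50 trials then 500 random trials;
    joint fusion during the first 200 trials. Non-match to sample: blocked
    pretraining on the two rewarded (right-arm) types until each is seen 6
    times, blocked training on all four types until each is seen 5 times,
    then 500 random trials; fusion during the training blocks only.
    Structural discrimination: likewise with 3 and 3 block repeats over the
    three rewarded and all six types.
    """
    if task == "cued_tmaze":
        pool = ("L", "R")
        return Schedule(
            phases=(
                Phase("blocks", 20, 50, pool, fusion=True),
                Phase("random", 1, 500, pool, fusion=False),
            ),
            fusion_window=(0, 200),
        )
    if spec is None:
        raise ValueError("sequence-task schedules need the maze spec for the trial-type pools")
    pool = tuple(spec.trial_types)
    rewarded = tuple(tt for tt in pool if spec.trial_types[tt].rewarded_side == "right")
    if task == "nms":
        reps_pre, reps_train = 6, 5
    elif task == "structural":
        reps_pre, reps_train = 3, 3
    else:
        raise ValueError(f"unknown task {task!r}")
    return Schedule(
        phases=(
            Phase("blocks", reps_pre * len(rewarded), 50, rewarded, fusion=False),
            Phase("blocks", reps_train * len(pool), 50, pool, fusion=True),
            Phase("random", 1, 500, pool, fusion=False),
        )
    )


@dataclass
class TrialResult:
    trial_index: int
    trial_type: str
    n_attempts: int
    first_attempt_correct: bool
    n_steps: int
    capped: bool


class _LogBuilder:
    """Column-wise accumulator for per-step records."""

    COLS = ("trial", "attempt", "step", "trial_type", "state", "action",
            "next_state", "reward", "z_star", "spawned", "fi_max", "oi_max")

    def __init__(self) -> None:
        self.cols: dict[str, list] = {c: [] for c in self.COLS}
        self.posteriors: list[np.ndarray] = []

    def add(self, trial: int, attempt: int, step: int, trial_type: str, rec: dict) -> None:
        c = self.cols
        c["trial"].append(trial)
        c["attempt"].append(attempt)
        c["step"].append(step)
        c["trial_type"].append(trial_type)
        c["state"].append(rec["state"])
        c["action"].append(rec["action"])
        c["next_state"].append(rec["next_state"])
        c["reward"].append(rec["reward"])
        c["z_star"].append(rec["z_star"])
        c["spawned"].append(rec["spawned"])
        c["fi_max"].append(rec["fi_max"])
        c["oi_max"].append(rec["oi_max"])
        self.posteriors.append(rec["posterior"])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cols)


@dataclass
class ExperimentLog:
    """Per-trial and per-step records of one agent run.

    ``posteriors`` holds the acting posterior vector of every step (aligned
    with ``steps`` rows); vectors grow as contexts are spawned.
    """

    trials: pd.DataFrame
    steps: pd.DataFrame
    posteriors: list[np.ndarray]
    config: dict = field(default_factory=dict)

    def random_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["phase_kind"] == "random"]

    def switch_trials(self) -> pd.DataFrame:
        """First trial of each block after the first, within blocked phases."""
        t = self.trials
        blocked = t[t["phase_kind"] != "random"]
        first = blocked.groupby(["phase", "block"], as_index=False).first()
        return first[first["block"] > 0].set_index("trial")


def run_trial(
    agent,
    spec: MazeSpec,
    trial_type: str,
    trial_index: int = 0,
    step_cap: int = 1000,
    log: _LogBuilder | None = None,
) -> TrialResult:
    """Run one trial to the correct arm end (or the step cap).

    Every arm-end visit is one attempt; a wrong end teleports the agent back
    to the start state with no learning on the teleport transition.
    """
    agent.begin_trial(trial_type)
    state = spec.start_state
    attempts, steps, attempt_idx = 0, 0, 0
    rewarded = False
    while steps < step_cap:
        action, nxt, r, rec = agent.step(state, trial_type)
        steps += 1
        if log is not None:
            log.add(trial_index, attempt_idx, steps, trial_type, rec)
        if spec.is_terminal(nxt):
            attempts += 1
            if nxt == spec.reward_location[trial_type]:
                rewarded = True
                break
            attempt_idx += 1
            state = spec.start_state  # teleport
        else:
            state = nxt
    agent.end_trial(rewarded)
    capped = not rewarded
    if capped and attempts == 0:
        attempts = 1  # the capped wander counts as one failed attempt
    return TrialResult(
        trial_index=trial_index,
        trial_type=trial_type,
        n_attempts=attempts,
        first_attempt_correct=rewarded and attempts == 1,
        n_steps=steps,
        capped=capped,
    )


def run_schedule(
    agent,
    spec: MazeSpec,
    schedule: Schedule,
    seed: int = 0,
    step_cap: int = 1000,
    record_steps: bool = True,
) -> ExperimentLog:
    """Execute the schedule's phases in order and return the full log.

    ``seed`` drives the trial-type sequence only; the agent carries its own
    generator, so one (agent seed, schedule seed, config) triple pins the
    entire run.
    """
    seq_rng = np.random.default_rng([seed, 7919])
    seq = schedule.trial_sequence(seq_rng)
    log = _LogBuilder() if record_steps else None
    rows = []
    for t, (pi, b, tt, fusion) in enumerate(seq):
        if hasattr(agent, "fusion_active"):
            agent.fusion_active = fusion
        res = run_trial(agent, spec, tt, trial_index=t, step_cap=step_cap, log=log)
        rows.append(
            (t, pi, schedule.phases[pi].kind, b, tt, fusion, res.n_attempts,
             res.first_attempt_correct, res.n_steps, res.capped)
        )
    trials = pd.DataFrame(
        rows,
        columns=["trial", "phase", "phase_kind", "block", "trial_type", "fusion",
                 "n_attempts", "first_attempt_correct", "n_steps", "capped"],
    )
    return ExperimentLog(
        trials=trials,
        steps=log.frame() if log is not None else pd.DataFrame(),
        posteriors=log.posteriors if log is not None else [],
        config={"schedule_seed": seed, "step_cap": step_cap},
    )


def metric_block_switch_attempts(
    log: ExperimentLog, last_k_switches: int, statistic: str = "mean"
) -> float:
    """Attempts needed on the first trial after each of the last k switches."""
    sw = log.switch_trials()
    if len(sw) < last_k_switches:
        raise ValueError(f"log has only {len(sw)} switches")
    vals = sw["n_attempts"].to_numpy()[-last_k_switches:]
    return float(np.median(vals) if statistic == "median" else np.mean(vals))


def metric_random_percent_correct(log: ExperimentLog, last_n_trials: int) -> float:
    """First-attempt percent correct over the last n random-phase trials."""
    rnd = log.random_trials()
    if len(rnd) < last_n_trials:
        raise ValueError(f"log has only {len(rnd)} random trials")
    correct = rnd["first_attempt_correct"].to_numpy()[-last_n_trials:]
    return float(100.0 * np.mean(correct))
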