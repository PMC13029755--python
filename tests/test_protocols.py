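"""Schedules, trial loop and behavioural metrics."""

import numpy as np
import pytest

from contextmaze.maze import build_cued_tmaze, build_sequence_task
from contextmaze.protocols import (
    Phase,
    Schedule,
    default_schedule,
    metric_block_switch_attempts,
    metric_random_percent_correct,
    run_schedule,
    run_trial,
)


class ScriptedAgent:
    """Deterministic stub: follows a fixed arm preference per attempt."""

    def __init__(self, spec, sides):
        self.spec = spec
        self.sides = list(sides)  # one entry per attempt: "left" | "right"
        self.attempt = 0
        self.z_star = 0
        self.last_acting_post = np.array([1.0])

    def begin_trial(self, trial_type):
        self.attempt = 0

    def end_trial(self, rewarded):
        pass

    def step(self, state, trial_type):
        spec = self.spec
        side = self.sides[min(self.attempt, len(self.sides) - 1)]
        if state < spec.junction:
            action = 0  # up
        elif state == spec.junction:
            action = 2 if side == "left" else 3
        elif state < spec.junction + spec.arm_length + 1:
            action = 2  # continue outward on the left arm
        else:
            action = 3
        nxt = spec.step(state, action)
        if spec.is_terminal(nxt):
            self.attempt += 1
        rec = {
            "state": state, "action": action, "next_state": nxt,
            "reward": spec.reward(nxt, trial_type), "z_star": 0, "spawned": False,
            "fi_max": np.nan, "oi_max": np.nan, "posterior": np.array([1.0]),
        }
        return action, nxt, spec.reward(nxt, trial_type), rec


@pytest.fixture(scope="module")
def spec():
    return build_cued_tmaze()


class TestRunTrial:
    def test_correct_first_attempt(self, spec):
        res = run_trial(ScriptedAgent(spec, ["left"]), spec, "L")
        assert res.n_attempts == 1
        assert res.first_attempt_correct

    def test_wrong_then_right(self, spec):
        res = run_trial(ScriptedAgent(spec, ["right", "left"]), spec, "L")
        assert res.n_attempts == 2
        assert not res.first_attempt_correct

    def test_step_cap_records_failure(self, spec):
        res = run_trial(ScriptedAgent(spec, ["right"]), spec, "L", step_cap=40)
        assert res.capped
        assert not res.first_attempt_correct
        assert res.n_attempts >= 1

    def test_uniform_agent_attempts_near_two(self, spec):
        """Uniform arm choice makes attempts geometric with p = 0.5."""
        from contextmaze.agents import AgentConfig, make_agent

        cfg = AgentConfig.for_task("cued_tmaze", "TD", seed=0, epsilon=1.0)
        agent = make_agent(spec, cfg)
        attempts = [run_trial(agent, spec, "L", step_cap=2000).n_attempts for _ in range(150)]
        assert 1.6 < np.mean(attempts) < 2.5


class TestSchedules:
    def test_block_sequence_round_robin(self):
        sched = Schedule(phases=(Phase("blocks", 2, 3, ("L", "R")),))
        seq = [tt for _, _, tt, _ in sched.trial_sequence(np.random.default_rng(0))]
        assert seq == ["L", "L", "L", "R", "R", "R"]

    def test_zero_off_probability_equals_plain_blocks(self):
        plain = Schedule(phases=(Phase("blocks", 4, 5, ("L", "R")),))
        prob = Schedule(phases=(Phase("probabilistic_blocks", 4, 5, ("L", "R"), 0.0),))
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        assert [t[2] for t in plain.trial_sequence(rng1)] == [
            t[2] for t in prob.trial_sequence(rng2)
        ]

    def test_probabilistic_blocks_flip_some_trials(self):
        sched = Schedule(phases=(Phase("probabilistic_blocks", 2, 100, ("L", "R"), 0.3),))
        seq = sched.trial_sequence(np.random.default_rng(2))
        first_block = [tt for _, b, tt, _ in seq if b == 0]
        frac_off = np.mean([tt != "L" for tt in first_block])
        assert 0.15 < frac_off < 0.45

    def test_random_phase_balanced(self):
        sched = Schedule(phases=(Phase("random", 1, 400, ("L", "R")),))
        seq = [t[2] for t in sched.trial_sequence(np.random.default_rng(3))]
        assert 0.4 < np.mean([tt == "L" for tt in seq]) < 0.6

    def test_fusion_window_restricts_fusion(self):
        sched = Schedule(
            phases=(Phase("blocks", 4, 50, ("L", "R"), fusion=True),),
            fusion_window=(0, 120),
        )
        seq = sched.trial_sequence(np.random.default_rng(0))
        fusion_flags = [f for _, _, _, f in seq]
        assert all(fusion_flags[:120]) and not any(fusion_flags[120:])

    def test_default_cued_tmaze_schedule(self):
        sched = default_schedule("cued_tmaze")
        assert sched.n_trials == 1500
        assert sched.fusion_window == (0, 200)

    def test_default_nms_schedule(self):
        spec = build_sequence_task("nms")
        sched = default_schedule("nms", spec)
        # 2 rewarded types x 6 reps, 4 types x 5 reps, then 500 random
        assert [p.n_blocks for p in sched.phases] == [12, 20, 1]
        assert sched.phases[0].trial_type_pool == ("A-A", "B-B")
        assert sched.phases[1].fusion and not sched.phases[0].fusion

    def test_default_structural_schedule(self):
        spec = build_sequence_task("structural")
        sched = default_schedule("structural", spec)
        assert [p.n_blocks for p in sched.phases] == [9, 18, 1]

    def test_determinism(self, spec):
        from contextmaze.agents import AgentConfig, make_agent

        sched = Schedule(phases=(Phase("blocks", 2, 10, ("L", "R")),))
        frames = []
        for _ in range(2):
            agent = make_agent(spec, AgentConfig.for_task("cued_tmaze", "FI", seed=5))
            frames.append(run_schedule(agent, spec, sched, seed=5).steps)
        assert frames[0].equals(frames[1])


class TestMetrics:
    def _log_with_switch_attempts(self, spec, attempts):
        """Build a log whose post-switch trials need the given attempt counts."""
        sides_by_trial = []
        sched = Schedule(phases=(Phase("blocks", len(attempts) + 1, 2, ("L", "R")),))
        seq = sched.trial_sequence(np.random.default_rng(0))
        k = 0
        for t, (_, b, tt, _) in enumerate(seq):
            correct = "left" if tt == "L" else "right"
            wrong = "right" if tt == "L" else "left"
            first_of_block = t % 2 == 0 and b > 0
            if first_of_block:
                n = attempts[k]; k += 1
                sides_by_trial.append([wrong] * (n - 1) + [correct])
            else:
                sides_by_trial.append([correct])

        class PerTrialScripted(ScriptedAgent):
            def __init__(self, spec):
                super().__init__(spec, ["left"])
                self.trial = -1

            def begin_trial(self, trial_type):
                super().begin_trial(trial_type)
                self.trial += 1
                self.sides = sides_by_trial[self.trial]

        return run_schedule(PerTrialScripted(spec), spec, sched, seed=0)

    def test_switch_attempts_arithmetic(self, spec):
        log = self._log_with_switch_attempts(spec, [2, 3, 2, 3])
        assert metric_block_switch_attempts(log, 4) == pytest.approx(2.5)
        assert metric_block_switch_attempts(log, 4, statistic="median") == pytest.approx(2.5)

    def test_perfect_agent_scores_one(self, spec):
        log = self._log_with_switch_attempts(spec, [1, 1, 1])
        assert metric_block_switch_attempts(log, 3) == 1.0

    def test_reactive_agent_scores_two(self, spec):
        log = self._log_with_switch_attempts(spec, [2, 2, 2])
        assert metric_block_switch_attempts(log, 3) == 2.0

    def test_percent_correct_scripted(self, spec):
        sched = Schedule(phases=(Phase("random", 1, 50, ("L",)),))
        log = run_schedule(ScriptedAgent(spec, ["left"]), spec, sched, seed=0)
        assert metric_random_percent_correct(log, 50) == 100.0
        log2 = run_schedule(ScriptedAgent(spec, ["right", "left"]), spec, sched, seed=0)
        assert metric_random_percent_correct(log2, 50) == 0.0

    def test_requires_enough_trials(self, spec):
        sched = Schedule(phases=(Phase("random", 1, 10, ("L",)),))
        log = run_schedule(ScriptedAgent(spec, ["left"]), spec, sched, seed=0)
        with pytest.raises(ValueError):
            metric_random_percent_correct(log, 100)

    def test_attempts_equal_arm_end_visits(self, spec):
        from contextmaze.agents import AgentConfig, make_agent

        agent = make_agent(spec, AgentConfig.for_task("cued_tmaze", "FI", seed=2))
        sched = Schedule(phases=(Phase("blocks", 1, 20, ("L",)),))
        log = run_schedule(agent, spec, sched, seed=2)
        ends = log.steps[log.steps["next_state"].isin([spec.left_end, spec.right_end])]
        assert len(ends) == log.trials["n_attempts"].sum()
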