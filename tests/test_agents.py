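"""Agent assembly: fusion arithmetic, baselines, spawning, mode contracts."""

import numpy as np
import pytest

from contextmaze.agents import (
    AgentConfig,
    BaselineAgent,
    InferenceAgent,
    agent_step,
    baseline_value,
    ideal_observer_posterior,
    infer_context,
    joint_posterior,
    make_agent,
    random_walk_pretrain,
    replay_trial,
)
from contextmaze.maze import build_cued_tmaze
from contextmaze.protocols import Phase, Schedule, run_schedule, run_trial


@pytest.fixture(scope="module")
def spec():
    return build_cued_tmaze()


class TestJointPosterior:
    def test_disjoint_certainties_average_to_half(self):
        np.testing.assert_allclose(
            joint_posterior(np.array([1.0, 0.0]), np.array([0.0, 1.0])), [0.5, 0.5]
        )

    def test_identical_posteriors_unchanged(self):
        p = np.array([0.3, 0.7])
        np.testing.assert_allclose(joint_posterior(p, p), p)

    def test_arithmetic_mean(self):
        np.testing.assert_allclose(
            joint_posterior(np.array([0.8, 0.2]), np.array([0.4, 0.6])), [0.6, 0.4]
        )

    def test_rejects_misaligned_labels(self):
        with pytest.raises(ValueError):
            joint_posterior(np.array([1.0]), np.array([0.5, 0.5]))


class TestIdealObserver:
    def test_true_context_gets_95(self):
        np.testing.assert_allclose(ideal_observer_posterior(0), [0.95, 0.05])
        np.testing.assert_allclose(ideal_observer_posterior(1), [0.05, 0.95])

    def test_constant_entropy(self):
        def entropy(p):
            return -(p * np.log(p)).sum()

        assert entropy(ideal_observer_posterior(0)) == pytest.approx(
            entropy(ideal_observer_posterior(1))
        )


class TestBaselines:
    def test_zero_weights_give_zero_value(self, spec):
        M = np.eye(spec.n_features)
        assert baseline_value("SR", M, np.zeros(spec.n_features), spec.observe(0, "L")) == 0.0

    def test_sr1_one_shot_learn_and_unlearn(self, spec):
        agent = BaselineAgent(spec, AgentConfig.for_task("cued_tmaze", "SR1", seed=0))
        end = spec.observe(spec.left_end, "L")
        idx = spec.left_end
        # simulate arriving at the rewarded left end
        agent.w[:] = 0
        agent.w[idx] += 1.0 * (1.0 - agent.w @ end)
        assert agent.w[idx] == pytest.approx(1.0)
        agent.w[idx] += 1.0 * (0.0 - agent.w @ end)
        assert agent.w[idx] == pytest.approx(0.0)

    def test_sr_incremental_reward_learning(self, spec):
        agent = BaselineAgent(spec, AgentConfig.for_task("cued_tmaze", "SR", seed=0))
        assert agent.cfg.reward_lr == 0.7
        end = spec.observe(spec.left_end, "L")
        agent.w[spec.left_end] += 0.7 * (1.0 - agent.w @ end)
        assert agent.w[spec.left_end] == pytest.approx(0.7)

    def test_baseline_runs_a_trial(self, spec):
        for mode in ("SR", "SR1", "TD"):
            agent = make_agent(spec, AgentConfig.for_task("cued_tmaze", mode, seed=0))
            res = run_trial(agent, spec, "L", step_cap=500)
            assert res.n_attempts >= 1


class TestInferenceAgent:
    def test_spawns_first_context_on_first_step(self, spec):
        agent = InferenceAgent(spec, AgentConfig.for_task("cued_tmaze", "FI", seed=0))
        assert agent.bank.active_count == 0
        agent_step(agent, 0, "L")
        assert agent.bank.active_count >= 1

    def test_context_bank_alignment(self, spec):
        agent = InferenceAgent(spec, AgentConfig.for_task("cued_tmaze", "FI", seed=0))
        run_trial(agent, spec, "L", step_cap=500)
        bank = agent.bank
        assert len(bank.smaps) == len(bank.cmaps) == len(bank.tdmaps)

    def test_acting_posterior_normalised_every_step(self, spec):
        agent = InferenceAgent(spec, AgentConfig.for_task("cued_tmaze", "JOINT", seed=0))
        agent.fusion_active = True
        state = 0
        for _ in range(200):
            _, nxt, _, rec = agent.step(state, "L")
            assert rec["posterior"].sum() == pytest.approx(1.0)
            assert (rec["posterior"] >= 0).all()
            state = 0 if spec.is_terminal(nxt) else nxt

    def test_never_exceeds_max_contexts(self, spec):
        cfg = AgentConfig.for_task("cued_tmaze", "FI", seed=3, max_contexts=3)
        agent = InferenceAgent(spec, cfg)
        sched = Schedule(phases=(Phase("blocks", 4, 20, ("L", "R")),))
        run_schedule(agent, spec, sched, seed=3)
        assert agent.bank.active_count <= 3

    def test_joint_without_window_matches_fi_trace(self, spec):
        """With fusion never active, JOINT must reproduce FI step for step."""
        sched = Schedule(phases=(Phase("blocks", 2, 20, ("L", "R"), fusion=False),))
        logs = {}
        for mode in ("FI", "JOINT"):
            agent = make_agent(spec, AgentConfig.for_task("cued_tmaze", mode, seed=7))
            logs[mode] = run_schedule(agent, spec, sched, seed=7)
        for col in ("state", "action", "next_state", "reward", "z_star"):
            assert logs["FI"].steps[col].tolist() == logs["JOINT"].steps[col].tolist()

    def test_infer_context_prefers_better_fitting_map(self, spec):
        agent = InferenceAgent(spec, AgentConfig.for_task("cued_tmaze", "FI", seed=0))
        from contextmaze.features import sr_terminal_update, sr_update

        agent.bank.spawn()
        agent.bank.spawn()
        for tt, z in (("L", 0), ("R", 1)):
            path = [0, 1, 2] + ([3, 4, 5] if tt == "L" else [6, 7, 8])
            for _ in range(40):
                for i in range(len(path) - 1):
                    sr_update(
                        agent.bank.smaps[z],
                        spec.observe(path[i], tt),
                        spec.observe(path[i + 1], tt),
                    )
                sr_terminal_update(agent.bank.smaps[z], spec.observe(path[-1], tt))
        belief = infer_context(agent, (spec.observe(0, "R"), spec.observe(1, "R")))
        assert belief.p[1] > belief.p[0]

    def test_infer_context_outcome_evidence(self, spec):
        agent = InferenceAgent(spec, AgentConfig.for_task("cued_tmaze", "OI", seed=0))
        from contextmaze.outcomes import oi_update

        agent.bank.spawn()
        agent.bank.spawn()
        for _ in range(20):
            oi_update(agent.bank.cmaps[0], 3, 0.81)
            oi_update(agent.bank.cmaps[1], 3, 0.0)
        belief = infer_context(agent, (3, 0.81))
        assert belief.z_star == 0


class TestReplay:
    def test_replay_reapplies_transitions_to_target_map_only(self, spec):
        agent = InferenceAgent(spec, AgentConfig.for_task("cued_tmaze", "REPLAY", seed=0))
        agent.bank.spawn()
        agent.bank.spawn()
        transitions = [
            (spec.observe(0, "L"), spec.observe(1, "L"), False),
            (spec.observe(1, "L"), spec.observe(2, "L"), False),
        ]
        other_before = agent.bank.smaps[0].M.copy()
        replay_trial(agent, transitions, oi_context=1)
        np.testing.assert_array_equal(agent.bank.smaps[0].M, other_before)
        assert np.abs(agent.bank.smaps[1].M).sum() > 0

    def test_replay_equivalent_to_direct_training(self, spec):
        from contextmaze.features import SuccessorMap, sr_update

        transitions = [
            (spec.observe(0, "L"), spec.observe(1, "L"), False),
            (spec.observe(1, "L"), spec.observe(2, "L"), False),
        ]
        agent = InferenceAgent(spec, AgentConfig.for_task("cued_tmaze", "REPLAY", seed=0))
        agent.bank.spawn()
        replay_trial(agent, transitions, oi_context=0)
        direct = SuccessorMap.fresh(spec.n_features)
        for a, b, _ in transitions:
            sr_update(direct, a, b)
        np.testing.assert_allclose(agent.bank.smaps[0].M, direct.M)

    def test_replay_rejects_unknown_context(self, spec):
        agent = InferenceAgent(spec, AgentConfig.for_task("cued_tmaze", "REPLAY", seed=0))
        with pytest.raises(ValueError):
            replay_trial(agent, [], oi_context=5)

    def test_replay_agent_runs(self, spec):
        agent = make_agent(spec, AgentConfig.for_task("cued_tmaze", "REPLAY", seed=0))
        sched = Schedule(phases=(Phase("blocks", 2, 10, ("L", "R")),))
        log = run_schedule(agent, spec, sched, seed=0, step_cap=400)
        assert len(log.trials) == 20


class TestExploration:
    def test_pretrained_map_approximates_random_policy_sr(self, spec):
        cfg = AgentConfig.for_task("cued_tmaze", "FI", seed=0)
        rng = np.random.default_rng(0)
        smap = random_walk_pretrain(spec, 30_000, cfg, rng)
        # analytic random-policy SR of the 9-state graph with wall bumps and
        # arm ends treated as ordinary states (inward move or stay)
        n = spec.n_locations
        P = np.zeros((n, n))
        for s in range(n):
            for a in range(4):
                nxt = spec.step(s, a)
                if spec.is_terminal(s):
                    inward = 3 if s == spec.left_end else 2
                    nxt = s - 1 if a == inward else s
                P[nxt, s] += 0.25
        expected = np.linalg.inv(np.eye(n) - 0.9 * P)
        learned = smap.M[:n, :n]
        # entries reach ~4.8; annealed gains leave a residual bias, so the
        # check is structural: strong agreement in shape, bounded error
        corr = np.corrcoef(learned.ravel(), expected.ravel())[0, 1]
        assert corr > 0.95
        assert np.abs(learned - expected).max() < 0.35 * expected.max()

    def test_cue_columns_never_touched(self, spec):
        smap = random_walk_pretrain(spec, 2_000, AgentConfig(), np.random.default_rng(1))
        assert not smap.M[:, spec.n_locations :].any()

    def test_zero_steps_is_zero_map(self, spec):
        smap = random_walk_pretrain(spec, 0, AgentConfig(), np.random.default_rng(2))
        assert not smap.M.any()

    def test_exploration_agent_seeds_new_contexts(self, spec):
        agent = InferenceAgent(spec, AgentConfig.for_task("cued_tmaze", "EXPLORATION", seed=0))
        agent_step(agent, 0, "L")
        assert np.abs(agent.bank.smaps[0].M).sum() > 0

    def test_ideal_observer_agent_runs(self, spec):
        agent = make_agent(spec, AgentConfig.for_task("cued_tmaze", "IDEAL_OBSERVER", seed=0))
        agent.fusion_active = True
        sched = Schedule(phases=(Phase("blocks", 2, 10, ("L", "R"), fusion=True),))
        log = run_schedule(agent, spec, sched, seed=0, step_cap=400)
        assert len(log.trials) == 20
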