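"""Splitter-cell simulation, incorrect-update counts, confidence gating."""

import numpy as np
import pandas as pd
import pytest

from contextmaze.agents import AgentConfig, ContextBank
from contextmaze.analysis import (
    collect_location_posteriors,
    confidence_gate,
    incorrect_update_count,
    simulated_firing,
    splitter_table,
)
from contextmaze.features import sr_terminal_update, sr_update
from contextmaze.maze import build_cued_tmaze
from contextmaze.protocols import ExperimentLog


@pytest.fixture(scope="module")
def spec():
    return build_cued_tmaze()


def trained_bank(spec, n_contexts=2):
    bank = ContextBank(spec, AgentConfig.for_task("cued_tmaze", "FI"))
    for tt, z in zip(("L", "R"), range(n_contexts)):
        bank.spawn()
        path = [0, 1, 2] + ([3, 4, 5] if tt == "L" else [6, 7, 8])
        for _ in range(60):
            for i in range(len(path) - 1):
                sr_update(bank.smaps[z], spec.observe(path[i], tt), spec.observe(path[i + 1], tt))
            sr_terminal_update(bank.smaps[z], spec.observe(path[-1], tt))
    return bank


def make_log(rows, posteriors, trial_rows):
    steps = pd.DataFrame(
        rows,
        columns=["trial", "attempt", "step", "trial_type", "state", "action",
                 "next_state", "reward", "z_star", "spawned", "fi_max", "oi_max"],
    )
    trials = pd.DataFrame(
        trial_rows,
        columns=["trial", "phase", "phase_kind", "block", "trial_type", "fusion",
                 "n_attempts", "first_attempt_correct", "n_steps", "capped"],
    )
    return ExperimentLog(trials=trials, steps=steps, posteriors=posteriors)


class TestSimulatedFiring:
    def test_certain_posteriors_equal_raw_occupancy_difference(self, spec):
        bank = trained_bank(spec)
        posts = {}
        for s in range(spec.n_locations):
            posts[("L", s)] = np.array([1.0, 0.0])
            posts[("R", s)] = np.array([0.0, 1.0])
        rec = simulated_firing(bank, posts, target_location=3, spec=spec)
        # with p(z)=1 on the preferred side, firing == raw occupancy there
        zi = rec.preferred_context
        ti = rec.trial_types.index(rec.preferred_trial_type)
        np.testing.assert_allclose(rec.firing[zi, ti], rec.raw_occupancy[zi, ti])

    def test_symmetric_posteriors_give_zero_probability_difference(self, spec):
        bank = trained_bank(spec)
        posts = {
            (tt, s): np.array([0.5, 0.5])
            for tt in ("L", "R")
            for s in range(spec.n_locations)
        }
        rec = simulated_firing(bank, posts, target_location=3, spec=spec)
        np.testing.assert_allclose(rec.probability_difference, 0.0, atol=1e-12)

    def test_probability_difference_bounded(self, spec):
        bank = trained_bank(spec)
        rng = np.random.default_rng(0)
        posts = {}
        for tt in ("L", "R"):
            for s in range(spec.n_locations):
                p = rng.dirichlet(np.ones(2))
                posts[(tt, s)] = p
        rec = simulated_firing(bank, posts, target_location=4, spec=spec)
        assert (np.abs(rec.probability_difference) <= 1.0).all()

    def test_untrained_bank_flagged(self, spec):
        bank = ContextBank(spec, AgentConfig.for_task("cued_tmaze", "FI"))
        bank.spawn()
        rec = simulated_firing(bank, {}, target_location=3, spec=spec)
        assert rec.flagged_untrained
        assert not rec.firing.any()

    def test_splitter_table_tidy_shape(self, spec):
        bank = trained_bank(spec)
        posts = {
            (tt, s): np.array([0.6, 0.4])
            for tt in ("L", "R")
            for s in range(spec.n_locations)
        }
        recs = [simulated_firing(bank, posts, t, spec=spec) for t in (3, 4)]
        table = splitter_table(recs, spec)
        assert len(table) == 2 * 2 * 2 * spec.n_locations
        assert set(table.columns) >= {"target_location", "state", "context", "firing"}


class TestIncorrectUpdates:
    def _row(self, trial, tt, z):
        return (trial, 0, 1, tt, 0, 0, 1, 0.0, z, False, np.nan, np.nan)

    def test_immediate_switch_counts_zero(self):
        rows = [self._row(t, "L", 0) for t in range(5)]
        rows += [self._row(t, "R", 1) for t in range(5, 10)]
        posts = [np.array([1.0])] * len(rows)
        trials = [(t, 0, "blocks", t // 5, "L" if t < 5 else "R", False, 1, True, 1, False) for t in range(10)]
        log = make_log(rows, posts, trials)
        assert incorrect_update_count(log, (5, 10)) == 0

    def test_never_switching_counts_every_update(self):
        rows = [self._row(t, "L", 0) for t in range(5)]
        rows += [self._row(t, "R", 0) for t in range(5, 8)]
        posts = [np.array([1.0])] * len(rows)
        trials = [(t, 0, "blocks", t // 5, "L" if t < 5 else "R", False, 1, True, 1, False) for t in range(8)]
        log = make_log(rows, posts, trials)
        assert incorrect_update_count(log, (5, 8)) == 3

    def test_fresh_context_never_incorrect(self):
        rows = [self._row(t, "L", 0) for t in range(5)]
        rows += [self._row(t, "R", 7) for t in range(5, 8)]  # brand-new context
        posts = [np.array([1.0])] * len(rows)
        trials = [(t, 0, "blocks", t // 5, "L" if t < 5 else "R", False, 1, True, 1, False) for t in range(8)]
        log = make_log(rows, posts, trials)
        assert incorrect_update_count(log, (5, 8)) == 0


class TestConfidenceGate:
    def _log(self, kind, fi_conf, oi_conf, n=20):
        rows = []
        posts = []
        for t in range(n):
            rows.append((t, 0, 1, "L", 0, 0, 1, 0.0, 0, False, fi_conf, oi_conf))
            posts.append(np.array([1.0]))
        trials = [(t, 0, kind, 0, "L", False, 1, True, 1, False) for t in range(n)]
        return make_log(rows, posts, trials)

    def test_identical_streams_gate_off(self):
        log = self._log("blocks", 0.8, 0.8)
        out = confidence_gate(log, log, threshold=0.1)
        assert not out["blocks"]["gate_on"]

    def test_sharp_oi_flat_fi_gates_on(self):
        log_fi = self._log("blocks", 0.5, np.nan)
        log_oi = self._log("blocks", np.nan, 1.0)
        out = confidence_gate(log_fi, log_oi, threshold=0.25)
        assert out["blocks"]["gate_on"]
        assert out["blocks"]["confidence_oi"] - out["blocks"]["confidence_fi"] == pytest.approx(0.5)

    def test_threshold_boundary(self):
        log_fi = self._log("random", 0.6, np.nan)
        log_oi = self._log("random", np.nan, 0.7)
        assert not confidence_gate(log_fi, log_oi, threshold=0.2)["random"]["gate_on"]
        assert confidence_gate(log_fi, log_oi, threshold=0.05)["random"]["gate_on"]


class TestCollectPosteriors:
    def test_means_grouped_by_location_and_type(self, spec):
        rows = [
            (0, 0, 1, "L", 0, 0, 1, 0.0, 0, False, np.nan, np.nan),
            (0, 0, 2, "L", 0, 0, 1, 0.0, 0, False, np.nan, np.nan),
            (1, 0, 1, "R", 0, 0, 1, 0.0, 1, False, np.nan, np.nan),
        ]
        posts = [np.array([0.8, 0.2]), np.array([0.6, 0.4]), np.array([0.1, 0.9])]
        trials = [
            (0, 0, "random", 0, "L", False, 1, True, 2, False),
            (1, 0, "random", 0, "R", False, 1, True, 1, False),
        ]
        log = make_log(rows, posts, trials)
        out = collect_location_posteriors(log, n_contexts=2)
        np.testing.assert_allclose(out[("L", 0)], [0.7, 0.3])
        np.testing.assert_allclose(out[("R", 0)], [0.1, 0.9])

    def test_incorrect_trials_excluded(self, spec):
        rows = [
            (0, 0, 1, "L", 0, 0, 1, 0.0, 0, False, np.nan, np.nan),
            (1, 0, 1, "L", 0, 0, 1, 0.0, 0, False, np.nan, np.nan),
        ]
        posts = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        trials = [
            (0, 0, "random", 0, "L", False, 1, True, 1, False),
            (1, 0, "random", 0, "L", False, 2, False, 2, False),
        ]
        log = make_log(rows, posts, trials)
        out = collect_location_posteriors(log, n_contexts=2)
        np.testing.assert_allclose(out[("L", 0)], [1.0, 0.0])
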