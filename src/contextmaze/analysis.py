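"""Neural-style and map-quality analyses.

Simulated "splitter cells": a cell is the predicted future occupancy of one
chosen location, read out of each context's successor map and weighted by
the posterior probability of that context at the animal-position being
analysed. Cells fire differently at the same place depending on the
inferred context, which is the hippocampal splitter-cell signature the
agents are probed for. Also provides the incorrect-update count around the
first block switch and the posterior-confidence gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import ContextBank
from .maze import MazeSpec
from .protocols import ExperimentLog

__all__ = [
    "SplitterRecord",
    "collect_location_posteriors",
    "simulated_firing",
    "splitter_table",
    "incorrect_update_count",
    "confidence_gate",
]


@dataclass
class SplitterRecord:
    """One simulated cell (a target location) and its context selectivity.

    ``firing[z, tt_index, s]`` is the posterior-weighted predicted future
    occupancy of the target location when the agent stands at ``s`` on
    trials of type ``tt``; ``probability_difference[s]`` is the mean
    posterior of the preferred context at ``s`` on its preferred trial type
    minus that on the non-preferred types.
    """

    target_location: int
    trial_types: tuple[str, ...]
    firing: np.ndarray  # (n_contexts, n_trial_types, n_states)
    raw_occupancy: np.ndarray  # same shape, without posterior weighting
    preferred_context: int
    preferred_trial_type: str
    probability_difference: np.ndarray  # (n_states,)
    flagged_untrained: bool = False


def collect_location_posteriors(
    log: ExperimentLog,
    n_contexts: int,
    correct_random_only: bool = True,
) -> dict[tuple[str, int], np.ndarray]:
    """Mean acting posterior per (trial type, state), padded to n_contexts.

    Uses the posterior active for action selection at each step. By default
    only first-attempt-correct random-phase trials contribute, mirroring the
    convention of analysing correct trials.
    """
    trials = log.trials
    if correct_random_only:
        keep = set(trials[(trials["phase_kind"] == "random") & trials["first_attempt_correct"]]["trial"])
    else:
        keep = set(trials["trial"])
    sums: dict[tuple[str, int], np.ndarray] = {}
    counts: dict[tuple[str, int], int] = {}
    steps = log.steps
    tr = steps["trial"].to_numpy()
    st = steps["state"].to_numpy()
    tt = steps["trial_type"].to_numpy()
    for i in range(len(steps)):
        if tr[i] not in keep:
            continue
        p = log.posteriors[i]
        key = (tt[i], int(st[i]))
        vec = np.zeros(n_contexts)
        vec[: min(len(p), n_contexts)] = p[:n_contexts]
        if key not in sums:
            sums[key] = vec
            counts[key] = 1
        else:
            sums[key] += vec
            counts[key] += 1
    return {k: sums[k] / counts[k] for k in sums}


def simulated_firing(
    bank: ContextBank,
    posteriors_by_location: dict[tuple[str, int], np.ndarray],
    target_location: int,
    spec: MazeSpec | None = None,
) -> SplitterRecord:
    """Posterior-weighted predicted occupancy of one location.

    For context z and state s, firing is the target-location row of M^z
    applied to φ(s) (the trial type's observation), multiplied by the mean
    posterior p(z) recorded at s on that trial type. The preferred context
    is the one with the larger total stem firing; its preferred trial type
    is where that firing is larger.
    """
    spec = spec if spec is not None else bank.spec
    n_z = bank.active_count
    tts = tuple(spec.trial_types)
    n_s = spec.n_locations
    raw = np.zeros((max(n_z, 1), len(tts), n_s))
    firing = np.zeros_like(raw)
    post = np.zeros_like(raw)
    for zi in range(n_z):
        row = bank.smaps[zi].M[target_location]
        for ti, tt in enumerate(tts):
            for s in range(n_s):
                occ = float(row @ spec.observe(s, tt, "full"))
                raw[zi, ti, s] = occ
                p = posteriors_by_location.get((tt, s))
                pz = float(p[zi]) if p is not None else 0.0
                post[zi, ti, s] = pz
                firing[zi, ti, s] = occ * pz
    stem = slice(0, spec.stem_length)
    untrained = n_z == 0 or not np.any(raw)
    stem_by_context = firing[:, :, stem].sum(axis=(1, 2)) if n_z else np.zeros(1)
    z_pref = int(np.argmax(stem_by_context))
    tt_pref_idx = int(np.argmax(firing[z_pref, :, stem].sum(axis=1))) if n_z else 0
    prob_diff = np.zeros(n_s)
    if n_z:
        others = [ti for ti in range(len(tts)) if ti != tt_pref_idx]
        for s in range(n_s):
            prob_diff[s] = post[z_pref, tt_pref_idx, s] - float(
                np.mean([post[z_pref, ti, s] for ti in others])
            )
    return SplitterRecord(
        target_location=target_location,
        trial_types=tts,
        firing=firing,
        raw_occupancy=raw,
        preferred_context=z_pref,
        preferred_trial_type=tts[tt_pref_idx],
        probability_difference=prob_diff,
        flagged_untrained=untrained,
    )


def splitter_table(records: list[SplitterRecord], spec: MazeSpec) -> pd.DataFrame:
    """Tidy frame: one row per cell x location x context x trial type."""
    rows = []
    for rec in records:
        n_z, n_t, n_s = rec.firing.shape
        for zi in range(n_z):
            for ti in range(n_t):
                for s in range(n_s):
                    rows.append(
                        (rec.target_location, s, zi, rec.trial_types[ti],
                         rec.firing[zi, ti, s], rec.raw_occupancy[zi, ti, s],
                         rec.probability_difference[s])
                    )
    return pd.DataFrame(
        rows,
        columns=["target_location", "state", "context", "trial_type",
                 "firing", "raw_occupancy", "probability_difference"],
    )


def incorrect_update_count(log: ExperimentLog, window: tuple[int, int]) -> int:
    """Map updates in ``window`` applied to a context of the wrong identity.

    Each context's established identity is the majority true trial type over
    its update steps before the window. A step inside the window counts as
    incorrect when the updated context has an established identity that
    mismatches the step's true trial type; freshly spawned contexts with no
    pre-window history never count.
    """
    lo, hi = window
    steps = log.steps
    pre = steps[steps["trial"] < lo]
    identity: dict[int, str] = {}
    if len(pre):
        maj = pre.groupby("z_star")["trial_type"].agg(lambda s: s.mode().iloc[0])
        identity = maj.to_dict()
    inside = steps[(steps["trial"] >= lo) & (steps["trial"] < hi)]
    z = inside["z_star"].to_numpy()
    tt = inside["trial_type"].to_numpy()
    count = 0
    for zi, ti in zip(z, tt):
        est = identity.get(int(zi))
        if est is not None and est != ti:
            count += 1
    return int(count)


def confidence_gate(
    log_fi: ExperimentLog,
    log_oi: ExperimentLog,
    threshold: float,
) -> dict[str, dict[str, float | bool]]:
    """Confidence-difference gate per phase kind.

    Confidence of a stream is its mean max-posterior over the phase's steps;
    fusion is gated on when the outcome stream is more confident than the
    feature stream by more than ``threshold``.
    """
    out: dict[str, dict[str, float | bool]] = {}
    for kind in ("blocks", "random"):
        conf = {}
        for name, lg, col in (("fi", log_fi, "fi_max"), ("oi", log_oi, "oi_max")):
            trials = set(lg.trials[lg.trials["phase_kind"] == kind]["trial"])
            sel = lg.steps[lg.steps["trial"].isin(trials)][col]
            vals = sel.to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:  # stream silent this phase: fall back to the acting posterior
                idx = lg.steps.index[lg.steps["trial"].isin(trials)]
                vals = np.array([np.max(lg.posteriors[i]) for i in idx])
            conf[name] = float(np.mean(vals)) if len(vals) else np.nan
        out[kind] = {
            "confidence_fi": conf["fi"],
            "confidence_oi": conf["oi"],
            "gate_on": bool(conf["oi"] - conf["fi"] > threshold),
        }
    return out
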