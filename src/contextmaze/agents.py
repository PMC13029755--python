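"""Agent assembly: inference streams, context banks, and baselines.

The inference agents (feature, outcome, joint and the joint variants) share
one context bank: context index z owns a successor map M^z, a convolved
reward map C^z and a TD value map TD^z, spawned together. Each step the
active strategy turns its evidence into a posterior over contexts (sticky-CRP
particle prior × map likelihood), selects the argmax context's TD map for
action, and hard-assigns map updates to that context.

Baselines (single-map SR, one-shot SR1, plain TD) skip inference entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .features import SuccessorMap, sr_terminal_update, sr_update
from .inference import LOG_2PI, ParticleSet, SCRPParams
from .maze import MazeSpec
from .outcomes import ConvolvedRewardMap, RewardBuffer, build_kernel, convolved_reward, oi_update
from .policy import TDMap, q_values, select_action, td_terminal_update, td_update

__all__ = [
    "AgentConfig",
    "ContextBank",
    "BeliefState",
    "InferenceAgent",
    "BaselineAgent",
    "make_agent",
    "infer_context",
    "joint_posterior",
    "ideal_observer_posterior",
    "random_walk_pretrain",
    "agent_step",
    "baseline_value",
    "replay_trial",
]

INFERENCE_MODES = ("FI", "OI", "JOINT", "REPLAY", "IDEAL_OBSERVER", "EXPLORATION")
BASELINE_MODES = ("SR", "SR1", "TD")


@dataclass
class AgentConfig:
    """Hyperparameter bundle; the defaults are the published task values.

    The structural-discrimination variant (six contexts) swaps in its own
    sCRP parameters via :meth:`for_task`.
    """

    mode: str = "FI"
    epsilon: float = 0.2
    gamma: float = 0.9
    obs_noise_var: float = 1.0
    init_context_probs: tuple[float, ...] = (1.0, 0.4, 0.1, 0, 0, 0, 0, 0, 0, 0)
    n_particles: int = 100
    history_window: int = 10
    max_contexts: int = 10
    # feature-inference stream
    fi_concentration: float = 0.5
    fi_stickiness: float = 5.0
    fi_init_var: float = 1.6
    fi_inference_var: float = 1.6
    # outcome-inference stream
    oi_concentration: float = 0.1
    oi_stickiness: float = 0.7
    oi_init_var: float = 1.6
    oi_lr_weight: float = 23.0
    oi_filter_len: int = 2
    # A convolved-reward estimate carries outcome information only when a
    # reward was seen in the window or some context expects one at the
    # centre state; below this threshold the step is outcome-silent.
    oi_signal_threshold: float = 0.05
    # Numerical floor for outcome likelihood variances (the maps track the
    # observed residual scatter themselves).
    oi_var_floor: float = 0.03
    # TD-map Kalman process noise: keeps a steady-state learning rate so
    # value maps can unlearn after a contingency change.
    td_process_noise: float = 0.0
    # Successor-map column process noise: same role for the feature maps
    # (wrongly absorbed entries wash out over own-context experience).
    sr_process_noise: float = 0.0
    # baselines
    reward_lr: float = 0.7  # α_r; SR1 uses 1.0
    # choice
    lookahead: str = "full"  # or "location_only"
    # joint fusion
    prior_order: tuple[str, ...] = ("feature", "outcome")
    seed: int = 0

    def fi_scrp(self) -> SCRPParams:
        return SCRPParams(self.fi_concentration, self.fi_stickiness, self.history_window, self.max_contexts)

    def oi_scrp(self) -> SCRPParams:
        return SCRPParams(self.oi_concentration, self.oi_stickiness, self.history_window, self.max_contexts)

    @classmethod
    def for_task(cls, task: str, mode: str = "FI", **overrides) -> "AgentConfig":
        cfg = cls(mode=mode)
        if task == "structural":
            cfg.fi_stickiness = 8.0
            cfg.oi_concentration = 0.8
        if mode == "SR1":
            cfg.reward_lr = 1.0
        for key, value in overrides.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config field {key!r}")
            setattr(cfg, key, value)
        return cfg


@dataclass
class BeliefState:
    """Posterior over active contexts plus (while below capacity) a new slot."""

    p: np.ndarray
    n_known: int

    @property
    def z_star(self) -> int:
        return int(np.argmax(self.p))

    @property
    def is_new(self) -> bool:
        return self.z_star >= self.n_known


class ContextBank:
    """Aligned per-context triplets (SuccessorMap, ConvolvedRewardMap, TDMap)."""

    def __init__(self, spec: MazeSpec, cfg: AgentConfig, template_smap: SuccessorMap | None = None):
        self.spec = spec
        self.cfg = cfg
        self.template_smap = template_smap
        self.smaps: list[SuccessorMap] = []
        self.cmaps: list[ConvolvedRewardMap] = []
        self.tdmaps: list[TDMap] = []

    def __len__(self) -> int:
        return len(self.smaps)

    @property
    def active_count(self) -> int:
        return len(self.smaps)

    def spawn(self) -> int:
        """Spawn one aligned triplet of fresh maps; returns its index."""
        cfg, spec = self.cfg, self.spec
        if self.template_smap is not None:
            smap = self.template_smap.copy()
        else:
            smap = SuccessorMap.fresh(
                spec.n_features,
                discount=cfg.gamma,
                inference_var=cfg.fi_inference_var,
                init_var=cfg.fi_init_var,
                obs_noise_var=cfg.obs_noise_var,
                col_process_noise=cfg.sr_process_noise,
            )
        self.smaps.append(smap)
        self.cmaps.append(
            ConvolvedRewardMap.fresh(
                spec.n_locations,
                init_var=cfg.oi_init_var,
                obs_noise_var=cfg.obs_noise_var,
                lr_weight=cfg.oi_lr_weight,
                filter_len=cfg.oi_filter_len,
            )
        )
        self.tdmaps.append(
            TDMap.fresh(
                spec.n_features,
                discount=cfg.gamma,
                init_var=cfg.fi_init_var,
                obs_noise_var=cfg.obs_noise_var,
                process_noise=cfg.td_process_noise,
            )
        )
        return len(self.smaps) - 1


def joint_posterior(p_feat: np.ndarray, p_out: np.ndarray) -> np.ndarray:
    """Average the feature and outcome posteriors element-wise, renormalised."""
    p_feat = np.asarray(p_feat, dtype=float)
    p_out = np.asarray(p_out, dtype=float)
    if p_feat.shape != p_out.shape:
        raise ValueError("posterior label sets are misaligned")
    p = 0.5 * (p_feat + p_out)
    return p / p.sum()


def ideal_observer_posterior(true_trial_index: int, n_contexts: int = 2) -> np.ndarray:
    """Told-the-answer posterior: 0.95 on the true context, 0.05 on the other."""
    if n_contexts != 2:
        raise ValueError("ideal observer is defined for 2-context tasks")
    p = np.full(2, 0.05)
    p[true_trial_index] = 0.95
    return p


def _normalise_logs(logp: np.ndarray) -> np.ndarray:
    m = logp.max()
    p = np.exp(logp - m)
    return p / p.sum()


class InferenceAgent:
    """Context-inferring agent (modes FI, OI, JOINT, REPLAY, IDEAL_OBSERVER,
    EXPLORATION).

    A single seeded generator drives, in order per step: the ε draw, the
    action draw (uniform action or tie-break), then particle sampling.
    """

    def __init__(self, spec: MazeSpec, cfg: AgentConfig, rng: np.random.Generator | None = None):
        if cfg.mode not in INFERENCE_MODES:
            raise ValueError(f"not an inference mode: {cfg.mode}")
        self.spec = spec
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        template = None
        if cfg.mode == "EXPLORATION":
            template = random_walk_pretrain(spec, 10_000, cfg, self.rng)
        self.bank = ContextBank(spec, cfg, template_smap=template)
        init_p = np.asarray(cfg.init_context_probs, dtype=float)
        self.particles = ParticleSet.initialise(cfg.n_particles, init_p, cfg.fi_scrp(), self.rng)
        # REPLAY keeps stream-separate particle sets; everything else shares one.
        self.oi_particles = (
            ParticleSet.initialise(cfg.n_particles, init_p, cfg.oi_scrp(), self.rng)
            if cfg.mode == "REPLAY"
            else None
        )
        self.kernel = build_kernel(cfg.gamma, cfg.oi_filter_len)
        self.buffer = RewardBuffer(cfg.oi_filter_len)
        self.fusion_active = False
        self.trial_type_order: list[str] = []  # for the ideal observer
        self.z_star = 0
        self.z_star_oi = 0
        self.last_fi_post: np.ndarray | None = None
        self.last_oi_post: np.ndarray | None = None
        self.last_acting_post: np.ndarray = np.array([1.0])
        self._trial_transitions: list[tuple[np.ndarray, np.ndarray, bool]] = []
        # Evidence completed on the previous step, awaiting inference.
        self._pending_fi: tuple[np.ndarray, np.ndarray] | None = None
        self._pending_oi: tuple[float, int] | None = None
        # Same transition plus rewards/terminal flag, awaiting absorption.
        self._pending_full: tuple | None = None
        # Outcome evidence scored this step, to be absorbed post-selection.
        self._scored_oi: tuple[float, int] | None = None
        # The outcome stream's standing belief between outcome events.
        self._oi_carried: np.ndarray | None = None

    # -- lifecycle --------------------------------------------------------

    @property
    def uses_fi(self) -> bool:
        return self.cfg.mode != "OI"

    def begin_trial(self, trial_type: str) -> None:
        self.buffer.clear()
        self.buffer.append(0.0, self.spec.start_state)
        self._trial_transitions = []
        if self.cfg.mode == "IDEAL_OBSERVER" and trial_type not in self.trial_type_order:
            self.trial_type_order.append(trial_type)

    def end_trial(self, rewarded: bool) -> None:
        if self.cfg.mode == "REPLAY" and rewarded:
            replay_trial(self, self._trial_transitions, self.z_star_oi)
        self._trial_transitions = []

    # -- belief machinery --------------------------------------------------

    def _support(self) -> int:
        """Belief-vector length: active contexts plus the new slot."""
        return self.bank.active_count + 1

    def _prior(self, params: SCRPParams, particles: ParticleSet | None = None) -> np.ndarray:
        pset = particles if particles is not None else self.particles
        pset.params = params
        return pset.prior_estimate(self.bank.active_count)

    def _fold(
        self, post: np.ndarray, lls: np.ndarray, always: bool = True, force: bool = False
    ) -> np.ndarray:
        """Redirect a winning new-slot onto a better-fitting existing map.

        The sCRP window forgets contexts that have not been used for y steps,
        so their prior — and hence posterior — goes to zero; a returning old
        context is then indistinguishable from "new". When the new slot wins
        and some existing map explains the evidence at least as well as a
        fresh map would, the verdict is read as that context returning and
        the new-slot mass is folded onto it; a fresh context is spawned only
        when nothing known fits better than blank. At capacity the fold is
        unconditional (no further map can be spawned).
        """
        n_known = self.bank.active_count
        if n_known == 0 or len(post) <= n_known:
            return post
        at_cap = n_known >= self.cfg.max_contexts
        if not force:
            if not at_cap and not always:
                return post
            new_wins = int(np.argmax(post)) == n_known
            # Reuse only a strictly better-than-blank fit: a map that merely
            # ties a fresh one carries no identity worth returning to.
            if not at_cap and not (new_wins and np.max(lls[:n_known]) > lls[n_known]):
                return post
        target = int(np.argmax(lls[:n_known]))
        folded = post[:n_known].copy()
        folded[target] += post[n_known]
        return folded / folded.sum()

    def _fi_logliks(self, phi_t: np.ndarray, phi_next: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        x = phi_t - cfg.gamma * phi_next
        size = self._support()
        lls = np.empty(size)
        var = cfg.fi_inference_var
        d = phi_t.size
        const = -0.5 * d * (LOG_2PI + math.log(var))
        for z, smap in enumerate(self.bank.smaps):
            r = phi_t - smap.M @ x
            lls[z] = const - 0.5 * (r @ r) / var
        if size > self.bank.active_count:  # the new slot: a fresh map
            if self.bank.template_smap is not None:
                r = phi_t - self.bank.template_smap.M @ x
            else:
                r = phi_t
            lls[-1] = const - 0.5 * (r @ r) / var
        return lls

    def _oi_logliks(self, location: int, cr: float) -> np.ndarray:
        cfg = self.cfg
        size = self._support()
        lls = np.empty(size)
        for z, cmap in enumerate(self.bank.cmaps):
            v = max(float(cmap.var[location]), cfg.oi_var_floor)
            lls[z] = -0.5 * (LOG_2PI + math.log(v)) - 0.5 * (cr - cmap.C[location]) ** 2 / v
        if size > self.bank.active_count:
            v = cfg.oi_init_var
            lls[-1] = -0.5 * (LOG_2PI + math.log(v)) - 0.5 * cr**2 / v
        return lls

    def _oi_informative(self, cr_evidence: tuple[float, int] | None) -> bool:
        """Whether a convolved-reward window carries any outcome signal.

        Outcome inference reacts to unexpected reward or to omission of an
        expected one. A window with no observed reward, centred on a state
        where no context predicts reward either, distinguishes nothing —
        every map explains it — so it contributes no evidence and leaves
        the belief untouched.
        """
        if cr_evidence is None:
            return False
        cr, center = cr_evidence
        tau = self.cfg.oi_signal_threshold
        if cr > tau:
            return True
        return any(abs(cmap.C[center]) > tau for cmap in self.bank.cmaps)

    def _pad(self, p: np.ndarray, size: int) -> np.ndarray:
        if len(p) == size:
            return p
        out = np.zeros(size)
        out[: len(p)] = p[:size].copy() if len(p) > size else p
        return out / out.sum()

    # -- the per-step cycle ------------------------------------------------

    def step(self, state: int, trial_type: str) -> tuple[int, int, float, dict]:
        """One full infer → absorb → act cycle.

        Inference consumes the evidence completed on the *previous* step
        (the last feature transition and/or the last convolved-reward
        estimate), and only then is that same evidence absorbed — as map
        updates — into the context selected in light of it. Scoring before
        absorbing keeps surprises at full strength, and assigning the
        update after re-inference means a block switch redirects learning
        to the right map from the transition that revealed it.

        Returns (action, next_state, reward_at_next_state, log record).
        """
        spec, cfg, rng = self.spec, self.cfg, self.rng
        mode = cfg.mode
        phi_t = spec.observe(state, trial_type, "full")

        # -- inference from pending evidence -------------------------------
        spawned = False
        if mode == "OI":
            acting = self._oi_only_inference(self._pending_oi)
        elif mode == "REPLAY":
            acting = self._replay_inference(self._pending_fi, self._pending_oi)
        else:
            acting = self._fi_family_inference(self._pending_fi, self._pending_oi, trial_type)
        fi_post, oi_post = self.last_fi_post, self.last_oi_post

        if acting is not None:
            belief = BeliefState(acting, self.bank.active_count)
            if belief.z_star >= self.bank.active_count:
                self.bank.spawn()
                spawned = True
            self.z_star = belief.z_star
            self.last_acting_post = acting
        if self.bank.active_count == 0:
            self.bank.spawn()
            spawned = True
        z = self.z_star

        # -- absorb the scored evidence -------------------------------------
        # Credit assignment differs by stream. Feature and value learning
        # follow the context that was *acting* when the transition happened
        # (its map made the prediction the transition tests; re-assigning
        # the update after a belief flip starves the acting map of exactly
        # the experience that would fix it). The purely reactive outcome
        # agent instead credits the context selected in light of the
        # evidence, so the reward found after a reversal trains the map of
        # the newly inferred context.
        if self._pending_full is not None:
            phi_a, phi_b, r_a, r_b, was_terminal, z_staged = self._pending_full
            z_c = z if mode == "OI" else z_staged
            if self.uses_fi:
                sr_update(self.bank.smaps[z_c], phi_a, phi_b)
                if was_terminal:
                    sr_terminal_update(self.bank.smaps[z_c], phi_b)
            td_update(self.bank.tdmaps[z_c], phi_a, phi_b, r_a)
            if was_terminal:
                td_terminal_update(self.bank.tdmaps[z_c], phi_b, r_b)
            self._pending_full = None

        # Outcome windows: reward-bearing ones always train the selected
        # context's map; zero windows only when they agree with it (in a
        # right-rewarded context, "nothing on the left approach" is correct
        # knowledge that sharpens the map). A window that conflicts with
        # every map acts purely as selection evidence — the map that
        # expected the reward keeps its expectation as context memory (the
        # context changed, the context's reward contingency did not).
        if self._scored_oi is not None:
            cr, center = self._scored_oi
            # Outcome maps are the outcome stream's own bookkeeping: they
            # absorb each window under the identity that stream inferred,
            # so disagreement with the feature stream during fusion cannot
            # mix reward knowledge across contexts.
            z_c = self.z_star_oi if mode in ("REPLAY", "JOINT") else z
            cmap = self.bank.cmaps[z_c]
            tau = cfg.oi_signal_threshold
            if cr > tau:
                oi_update(cmap, center, cr)
            elif abs(cr - cmap.C[center]) <= tau and cmap.C.max() > tau:
                # A zero window sharpens a map only once that map knows
                # where its reward is ("the rest of the story"); otherwise a
                # blank context would accumulate a spurious confidence edge
                # over a genuinely fresh one.
                oi_update(cmap, center, cr)
            self._scored_oi = None

        # -- act with the inferred context's TD map -------------------------
        q = q_values(self.bank.tdmaps[z], state, trial_type, spec, lookahead=cfg.lookahead)
        action = select_action(q, cfg.epsilon, rng)

        next_state = spec.step(state, action)
        phi_next = spec.observe(next_state, trial_type, "full")
        r_next = spec.reward(next_state, trial_type)
        terminal = spec.is_terminal(next_state)
        moved = next_state != state
        if moved:
            # The outcome window advances per state visit: a wall bump
            # revisits nothing, and letting it duplicate buffer entries
            # would shift which state each convolved reward is credited to.
            self.buffer.append(r_next, next_state)
        else:
            # A rejected move is not evidence, but the self-transition TD
            # delta −(1−γ)V(s) correctly discounts time spent against a
            # wall and steers the greedy policy away from it.
            td_update(self.bank.tdmaps[z], phi_t, phi_t, spec.reward(state, trial_type))

        new_cr = convolved_reward(self.buffer, self.kernel) if mode != "FI" else None

        # -- stage this step's evidence for the next inference --------------
        if moved:
            self._pending_fi = (phi_t, phi_next)
            self._pending_full = (
                phi_t, phi_next, spec.reward(state, trial_type), r_next, terminal, z
            )
            if self.uses_fi:
                self._trial_transitions.append((phi_t, phi_next, terminal))
        else:
            self._pending_fi = None
            self._pending_full = None
        if mode != "FI":
            self._pending_oi = new_cr if self._oi_informative(new_cr) else None

        log = {
            "state": state,
            "action": action,
            "next_state": next_state,
            "reward": r_next,
            "z_star": z,
            "spawned": spawned,
            "fi_max": float(np.max(fi_post)) if fi_post is not None else np.nan,
            "oi_max": float(np.max(oi_post)) if oi_post is not None else np.nan,
            "posterior": self.last_acting_post.copy(),
        }
        return action, next_state, r_next, log

    # -- mode-specific inference helpers ----------------------------------

    def _fi_family_inference(
        self,
        fi_evidence: tuple[np.ndarray, np.ndarray] | None,
        oi_evidence: tuple[float, int] | None,
        trial_type: str,
    ) -> np.ndarray | None:
        """FI, JOINT, IDEAL_OBSERVER and EXPLORATION share this path."""
        cfg = self.cfg
        fuse = cfg.mode in ("JOINT", "IDEAL_OBSERVER") and self.fusion_active
        has_oi = fuse and (cfg.mode == "IDEAL_OBSERVER" or oi_evidence is not None)
        if fi_evidence is None and not has_oi:
            self.last_fi_post = None
            self.last_oi_post = None
            return None
        size = self._support()
        if fuse:
            prior = 0.5 * (self._prior(cfg.fi_scrp()) + self._prior(cfg.oi_scrp()))
            prior /= prior.sum()
        else:
            prior = self._prior(cfg.fi_scrp())
        logp = np.log(np.maximum(prior, 1e-300))

        fi_post = fi_lls = None
        if fi_evidence is not None:
            fi_lls = self._fi_logliks(*fi_evidence)
            fi_post = self._fold(_normalise_logs(logp + fi_lls), fi_lls, always=False)
        self.last_fi_post = fi_post

        oi_post = oi_lls = None
        if has_oi:
            if cfg.mode == "IDEAL_OBSERVER":
                idx = self.trial_type_order.index(trial_type)
                oi_post = self._pad(ideal_observer_posterior(idx), size)
                oi_lls = np.log(np.maximum(oi_post, 1e-300))
                oi_post = self._fold(oi_post, oi_lls)
            else:
                cr, center = oi_evidence
                oi_lls = self._oi_logliks(center, cr)
                oi_post = self._fold(_normalise_logs(logp + oi_lls), oi_lls)
                self._scored_oi = oi_evidence
                z_oi = int(np.argmax(oi_post))
                if z_oi >= self.bank.active_count:
                    self.bank.spawn()
                self.z_star_oi = z_oi
        self.last_oi_post = oi_post

        if fi_post is None:
            acting = oi_post
        elif oi_post is None:
            acting = fi_post
        else:
            # One stream may have folded its new slot onto an existing map;
            # force-fold the other to the same support before averaging.
            if len(fi_post) > len(oi_post):
                fi_post = self._fold(fi_post, fi_lls, force=True)
                self.last_fi_post = fi_post
            elif len(oi_post) > len(fi_post):
                oi_post = self._fold(oi_post, oi_lls, force=True)
                self.last_oi_post = oi_post
            acting = joint_posterior(fi_post, oi_post)

        # Advance the (shared) particle set once per stream. The outcome
        # stream's belief persists between outcome events, so during fusion
        # it keeps contributing its standing verdict to the joint prior —
        # otherwise the far more frequent feature advances would wash the
        # outcome stamps out of the windows within a few steps.
        if oi_post is not None:
            self._oi_carried = oi_post
        carried = self._oi_carried if fuse else None
        if carried is not None and fi_post is not None and len(carried) != len(fi_post):
            carried = self._pad(carried, len(fi_post))
            self._oi_carried = carried
        for stream in cfg.prior_order:
            if stream == "feature" and fi_post is not None:
                self.particles.advance(fi_post, self.rng)
            elif stream == "outcome":
                if oi_post is not None:
                    self.particles.advance(oi_post, self.rng)
                elif carried is not None:
                    self.particles.advance(carried, self.rng)
        return acting

    def _oi_only_inference(self, cr_evidence: tuple[float, int] | None) -> np.ndarray | None:
        if cr_evidence is None:
            self.last_fi_post = None
            self.last_oi_post = None
            return None
        cr, center = cr_evidence
        prior = self._prior(self.cfg.oi_scrp())
        logp = np.log(np.maximum(prior, 1e-300))
        lls = self._oi_logliks(center, cr)
        oi_post = self._fold(_normalise_logs(logp + lls), lls)
        self._scored_oi = cr_evidence
        self.last_fi_post = None
        self.last_oi_post = oi_post
        self.particles.advance(oi_post, self.rng)
        return oi_post

    def _replay_inference(
        self,
        fi_evidence: tuple[np.ndarray, np.ndarray] | None,
        cr_evidence: tuple[float, int] | None,
    ) -> np.ndarray | None:
        """FI acts; an independent OI stream labels the trial for replay."""
        cfg = self.cfg
        fi_post = None
        if fi_evidence is not None:
            prior = self._prior(cfg.fi_scrp())
            logp = np.log(np.maximum(prior, 1e-300))
            lls = self._fi_logliks(*fi_evidence)
            fi_post = self._fold(_normalise_logs(logp + lls), lls, always=False)
            self.particles.advance(fi_post, self.rng)
        self.last_fi_post = fi_post
        oi_post = None
        if cr_evidence is not None:
            cr, center = cr_evidence
            oi_prior = self._prior(cfg.oi_scrp(), self.oi_particles)
            oi_logp = np.log(np.maximum(oi_prior, 1e-300))
            lls = self._oi_logliks(center, cr)
            oi_post = self._fold(_normalise_logs(oi_logp + lls), lls)
            self._scored_oi = cr_evidence
            self.oi_particles.advance(oi_post, self.rng)
            z_oi = int(np.argmax(oi_post))
            if z_oi >= self.bank.active_count:
                self.bank.spawn()
            self.z_star_oi = z_oi
        self.last_oi_post = oi_post
        return fi_post


def replay_trial(
    agent: InferenceAgent,
    trial_transitions: list[tuple[np.ndarray, np.ndarray, bool]],
    oi_context: int,
) -> InferenceAgent:
    """Re-apply a rewarded trial's feature transitions to one context's map.

    The outcome stream's inferred trial identity is accepted as ground truth
    and every stored transition is replayed, in order, into that context's
    successor map only.
    """
    if oi_context >= agent.bank.active_count:
        raise ValueError("replay target context does not exist")
    smap = agent.bank.smaps[oi_context]
    for phi_t, phi_next, terminal in trial_transitions:
        sr_update(smap, phi_t, phi_next)
        if terminal:
            sr_terminal_update(smap, phi_next)
    return agent


def infer_context(agent: InferenceAgent, evidence: tuple) -> BeliefState:
    """Stand-alone posterior from one piece of evidence.

    ``evidence`` is ``(phi_t, phi_next)`` for the feature stream or
    ``(location, cr)`` for the outcome stream (an int location first).
    Does not advance the particle set and does not spawn maps.
    """
    first = evidence[0]
    if np.isscalar(first) or (isinstance(first, (int, np.integer))):
        location, cr = evidence
        prior = agent._prior(agent.cfg.oi_scrp())
        lls = agent._oi_logliks(int(location), float(cr))
    else:
        phi_t, phi_next = evidence
        prior = agent._prior(agent.cfg.fi_scrp())
        lls = agent._fi_logliks(np.asarray(phi_t, float), np.asarray(phi_next, float))
    p = _normalise_logs(np.log(np.maximum(prior, 1e-300)) + lls)
    return BeliefState(p, agent.bank.active_count)


class BaselineAgent:
    """Single-map comparison agents: SR, one-shot SR1, and plain TD."""

    def __init__(self, spec: MazeSpec, cfg: AgentConfig, rng: np.random.Generator | None = None):
        if cfg.mode not in BASELINE_MODES:
            raise ValueError(f"not a baseline mode: {cfg.mode}")
        self.spec = spec
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        d = spec.n_features
        self.smap = SuccessorMap.fresh(
            d, discount=cfg.gamma, inference_var=cfg.fi_inference_var,
            init_var=cfg.fi_init_var, obs_noise_var=cfg.obs_noise_var,
        )
        self.w = np.zeros(d)
        self.tdmap = TDMap.fresh(d, discount=cfg.gamma, init_var=cfg.fi_init_var, obs_noise_var=cfg.obs_noise_var)
        self.z_star = 0
        self.last_acting_post = np.array([1.0])
        self.last_fi_post = None
        self.last_oi_post = None

    def begin_trial(self, trial_type: str) -> None:
        pass

    def end_trial(self, rewarded: bool) -> None:
        pass

    def _q(self, state: int, trial_type: str) -> dict[int, float]:
        spec = self.spec
        q = {}
        for a in spec.legal_actions(state):
            phi = spec.observe(spec.step(state, a), trial_type, "full")
            if self.cfg.mode == "TD":
                q[a] = self.tdmap.value(phi)
            else:
                q[a] = float((self.smap.M @ phi) @ self.w)
        return q

    def step(self, state: int, trial_type: str) -> tuple[int, int, float, dict]:
        spec, cfg, rng = self.spec, self.cfg, self.rng
        phi_t = spec.observe(state, trial_type, "full")
        action = select_action(self._q(state, trial_type), cfg.epsilon, rng)
        next_state = spec.step(state, action)
        phi_next = spec.observe(next_state, trial_type, "full")
        r_next = spec.reward(next_state, trial_type)
        terminal = spec.is_terminal(next_state)
        if cfg.mode == "TD":
            td_update(self.tdmap, phi_t, phi_next, spec.reward(state, trial_type))
            if terminal:
                td_terminal_update(self.tdmap, phi_next, r_next)
        else:
            sr_update(self.smap, phi_t, phi_next)
            if terminal:
                sr_terminal_update(self.smap, phi_next)
            lr = 1.0 if cfg.mode == "SR1" else cfg.reward_lr
            obs = phi_next != 0
            self.w[obs] += lr * (r_next - float(self.w @ phi_next))
        log = {
            "state": state, "action": action, "next_state": next_state,
            "reward": r_next, "z_star": 0, "spawned": False,
            "fi_max": np.nan, "oi_max": np.nan, "posterior": np.array([1.0]),
        }
        return action, next_state, r_next, log


def baseline_value(mode: str, M: np.ndarray, w: np.ndarray, phi: np.ndarray) -> float:
    """SR/SR1 state value V(s) = (Mφ(s))·w."""
    if mode not in ("SR", "SR1"):
        raise ValueError("baseline_value is defined for SR and SR1")
    return float((np.asarray(M) @ np.asarray(phi, float)) @ np.asarray(w, float))


def random_walk_pretrain(
    spec: MazeSpec,
    n_steps: int,
    cfg: AgentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SuccessorMap:
    """Random-walk SR of the maze graph without cues or rewards.

    The walker takes uniformly random legal actions; arm ends behave as
    ordinary wall-bounded states so the walk never terminates. The returned
    map (with its Kalman Σ) seeds new contexts in the EXPLORATION variant.
    """
    cfg = cfg or AgentConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    smap = SuccessorMap.fresh(
        spec.n_features, discount=cfg.gamma, inference_var=cfg.fi_inference_var,
        init_var=cfg.fi_init_var, obs_noise_var=cfg.obs_noise_var,
    )
    loc = spec._loc_obs  # location one-hots, cue entries zero
    # Walk on the graph with terminal self-loops removed: from an arm end the
    # only moves are back inward (mirror of the outward move) or staying put.
    state = spec.start_state
    for _ in range(n_steps):
        actions = tuple(range(4))
        a = actions[rng.integers(len(actions))]
        nxt = spec.step(state, a)
        if spec.is_terminal(state):
            # undo the absorbing self-loop: allow stepping back inward
            inward = 3 if state == spec.left_end else 2  # RIGHT from left arm, LEFT from right arm
            nxt = spec.transition[state, a] if a != inward else state - 1
            if a == inward:
                nxt = state - 1
        sr_update(smap, loc[state], loc[nxt])
        state = nxt
    return smap


def make_agent(spec: MazeSpec, cfg: AgentConfig, rng: np.random.Generator | None = None):
    """Factory over all agent modes."""
    if cfg.mode in BASELINE_MODES:
        return BaselineAgent(spec, cfg, rng)
    return InferenceAgent(spec, cfg, rng)


def agent_step(agent, env_state: int, trial_type: str):
    """Run one full agent cycle; returns (action, log record)."""
    action, _, _, log = agent.step(env_state, trial_type)
    return action, log
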