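"""Per-context TD value maps and ε-greedy action selection.

Choice is deliberately separated from inference: whichever context a
strategy infers, a context-specific linear TD map over features supplies
one-step-lookahead action values, and actions are ε-greedy over those.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import KalmanState
from .maze import MazeSpec

__all__ = ["TDMap", "td_update", "td_terminal_update", "q_values", "select_action"]


@dataclass
class TDMap:
    """Linear state-value map: V(φ) = TD·φ.

    The value of a state is its discounted expected future reward counting
    the reward of the occupied state itself, so a rewarded terminal has
    value equal to its reward.
    """

    td: np.ndarray
    kalman: KalmanState
    discount: float = 0.9

    @classmethod
    def fresh(
        cls,
        dim: int,
        discount: float = 0.9,
        init_var: float = 1.6,
        obs_noise_var: float = 1.0,
        process_noise: float = 0.005,
    ) -> "TDMap":
        """New zero map. The small default process noise keeps a steady-state
        Kalman gain so learnt values can also be unlearnt after a reversal."""
        return cls(
            td=np.zeros(dim),
            kalman=KalmanState.identity(
                dim, init_var=init_var, obs_noise_var=obs_noise_var, process_noise=process_noise
            ),
            discount=discount,
        )

    def value(self, phi: np.ndarray) -> float:
        return float(self.td @ phi)

    def copy(self) -> "TDMap":
        return TDMap(self.td.copy(), self.kalman.copy(), self.discount)


def td_update(tdmap: TDMap, phi_t: np.ndarray, phi_next: np.ndarray, r: float) -> TDMap:
    """Kalman-gain TD(0) update, in place.

    δ = r − TD·φ_t + γ·TD·φ_{t+1} with r the reward of the occupied state;
    the Kalman regressor is the current state features φ_t.
    """
    phi_t = np.asarray(phi_t, dtype=float)
    phi_next = np.asarray(phi_next, dtype=float)
    delta = r - tdmap.td @ phi_t + tdmap.discount * (tdmap.td @ phi_next)
    k = tdmap.kalman.gain(phi_t)
    tdmap.td += k * delta
    return tdmap


def td_terminal_update(tdmap: TDMap, phi_term: np.ndarray, r: float) -> TDMap:
    """Zero-continuation update at an attempt-ending state: δ = r − TD·φ."""
    return td_update(tdmap, phi_term, np.zeros_like(phi_term), r)


def q_values(
    tdmap: TDMap,
    state: int,
    trial_type: str,
    spec: MazeSpec,
    lookahead: str = "full",
) -> dict[int, float]:
    """One-step-lookahead action values Q(a) = TD·φ(step(state, a)).

    Only legal actions are scored. ``lookahead="full"`` queries the
    environment's observation for the current trial (the agent is granted
    the transition dynamics p(φ_{t+1}|φ_t, a)); ``lookahead="location_only"``
    strips cue features from the lookahead observation.
    """
    channel = "full" if lookahead == "full" else "location_only"
    q: dict[int, float] = {}
    for a in spec.legal_actions(state):
        nxt = spec.step(state, a)
        phi = spec.observe(nxt, trial_type, "full")
        if channel == "location_only":
            phi = phi.copy()
            phi[spec.n_locations :] = 0.0
        q[a] = float(tdmap.td @ phi)
    return q


def select_action(q: dict[int, float], epsilon: float, rng: np.random.Generator) -> int:
    """ε-greedy with uniform random tie-breaking among maximisers."""
    if not q:
        raise ValueError("empty action-value map")
    actions = list(q)
    if epsilon > 0 and rng.random() < epsilon:
        return actions[rng.integers(len(actions))]
    vals = np.array([q[a] for a in actions])
    best = np.flatnonzero(vals == vals.max())
    if len(best) == 1:
        return actions[best[0]]
    return actions[best[rng.integers(len(best))]]
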