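"""Context-specific successor-feature maps.

A successor map M predicts the discounted future occupancy of every feature
given the currently observed features, ψ(s) = Mφ(s). Maps are learnt with a
delta rule whose learning rate is the Kalman gain, and context likelihoods
are evaluated from the feature-transition residual φ_t − (ψ(s_t) − γψ(s_{t+1}))
under a fixed-variance diagonal Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import gaussian_loglik

__all__ = [
    "SuccessorMap",
    "successor_features",
    "sr_update",
    "sr_terminal_update",
    "fi_loglik",
    "cue_representation_score",
]


@dataclass
class SuccessorMap:
    """Successor map M with per-column Kalman uncertainty.

    Every entry of column j is modelled as Gaussian with a column-specific
    variance σj², so each column carries its own scalar Kalman filter: the
    gain k_j = σj²/(σj² + σn²) anneals with how often that column's feature
    has been observed, keeping weakly-scaled feature columns from being
    starved by strongly-scaled ones in the same transition.
    ``inference_var`` is the fixed residual variance σr² used for context
    likelihoods (the tracked σj² govern only learning rates). New maps start
    at zero (nothing unseen has predicted occupancy) with σj² = σ0².
    """

    M: np.ndarray
    col_var: np.ndarray
    obs_noise_var: float = 1.0
    inference_var: float = 1.6
    discount: float = 0.9
    #: Small per-observation inflation of the column variances. Keeps a
    #: steady-state gain so stale entries (e.g. another context's cue
    #: wrongly absorbed during a block switch) wash out over later
    #: own-context experience instead of freezing in.
    col_process_noise: float = 0.0

    @classmethod
    def fresh(
        cls,
        dim: int,
        discount: float = 0.9,
        inference_var: float = 1.6,
        init_var: float = 1.6,
        obs_noise_var: float = 1.0,
        col_process_noise: float = 0.0,
    ) -> "SuccessorMap":
        return cls(
            M=np.zeros((dim, dim)),
            col_var=np.full(dim, float(init_var)),
            obs_noise_var=obs_noise_var,
            inference_var=inference_var,
            discount=discount,
            col_process_noise=col_process_noise,
        )

    def copy(self) -> "SuccessorMap":
        return SuccessorMap(
            self.M.copy(), self.col_var.copy(), self.obs_noise_var,
            self.inference_var, self.discount, self.col_process_noise,
        )


def successor_features(smap: SuccessorMap, phi: np.ndarray) -> np.ndarray:
    """ψ = Mφ: predicted discounted future occupancy of every feature."""
    return smap.M @ phi


def _column_gain(smap: SuccessorMap, phi_t: np.ndarray) -> np.ndarray:
    # Per-column scalar Kalman gain k_j = σj²/(σj²+σn²): confidence in a
    # column grows with how often its feature has been observed, not with
    # the feature's magnitude, so strongly-scaled cue columns anneal at the
    # same pace as location columns. Only observed columns receive
    # information, so only their uncertainty shrinks.
    v = smap.col_var
    if smap.col_process_noise > 0:
        v = v + np.where(phi_t != 0, smap.col_process_noise, 0.0)
    k = v / (v + smap.obs_noise_var)
    observed = phi_t != 0
    smap.col_var = np.where(observed, v * (1.0 - k), v)
    return np.where(observed, k, 0.0)


def sr_update(smap: SuccessorMap, phi_t: np.ndarray, phi_next: np.ndarray) -> SuccessorMap:
    """Delta-rule update M ← M + δ ⊗ (k ⊙ g), in place.

    δ = φ_t + γψ(s_{t+1}) − ψ(s_t) is the row error; k is the per-column
    Kalman gain; g_i = φ_{i,t}/x_t with x_t the total squared feature mass
    (Σ_i φ_{i,t}²) normalises for feature overrepresentation and for how
    many features are present. The combination δ ⊗ (k ⊙ g) is the
    minimum-norm least-squares correction scaled by the annealed gains, so
    the per-step contraction never exceeds max k_j < 1. Only columns of
    observed features move.
    """
    phi_t = np.asarray(phi_t, dtype=float)
    phi_next = np.asarray(phi_next, dtype=float)
    n_obs = float(phi_t @ phi_t)
    if n_obs == 0:
        raise ValueError("phi_t has no observed features")
    gamma = smap.discount
    psi_t = smap.M @ phi_t
    psi_next = smap.M @ phi_next
    delta = phi_t + gamma * psi_next - psi_t
    k = _column_gain(smap, phi_t)
    g = phi_t / n_obs
    smap.M += np.outer(delta, k * g)
    return smap


def sr_terminal_update(smap: SuccessorMap, phi_term: np.ndarray) -> SuccessorMap:
    """Absorption update at an attempt-ending state.

    The terminal state has no successors within the attempt, so its own
    column is trained toward the zero-continuation target: δ = φ − ψ(φ).
    Nothing is learnt across the teleport back to the start.
    """
    phi_term = np.asarray(phi_term, dtype=float)
    n_obs = float(phi_term @ phi_term)
    if n_obs == 0:
        raise ValueError("phi_term has no observed features")
    delta = phi_term - smap.M @ phi_term
    k = _column_gain(smap, phi_term)
    g = phi_term / n_obs
    smap.M += np.outer(delta, k * g)
    return smap


def fi_loglik(smap: SuccessorMap, phi_t: np.ndarray, phi_next: np.ndarray) -> float:
    """Log-likelihood of the observed transition under this context's map.

    p(φ_t | z) is Gaussian around the map's reconstruction ψ(s_t) − γψ(s_{t+1})
    with fixed per-dimension variance σr².
    """
    phi_t = np.asarray(phi_t, dtype=float)
    phi_next = np.asarray(phi_next, dtype=float)
    recon = smap.M @ (phi_t - smap.discount * phi_next)
    return gaussian_loglik(phi_t - recon, smap.inference_var)


def cue_representation_score(
    smap: SuccessorMap,
    phi_start: np.ndarray,
    phi_cue: np.ndarray,
    cue_index: int,
) -> float:
    """How well a cue is predicted from the pre-cue state.

    Rearranging the one-step consistency ψ(start) = φ(start) + γψ(cue_state)
    of a converged map, the map's implied next-step occupancy of the cue is
    (ψ(start) − φ(start))/γ at the cue component. The score is that implied
    occupancy minus the observed cue value: 0 means the cue's future
    occupancy is perfectly predicted from the pre-cue state, > 0
    over-represented, < 0 under-represented (an untrained map scores minus
    the observed cue value).
    """
    phi_start = np.asarray(phi_start, dtype=float)
    phi_cue = np.asarray(phi_cue, dtype=float)
    psi_start = smap.M @ phi_start
    implied = (psi_start[cue_index] - phi_start[cue_index]) / smap.discount
    return float(implied - phi_cue[cue_index])
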