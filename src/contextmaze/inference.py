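"""Shared probabilistic machinery for context inference.

Provides the Kalman-filter learning-rate computation used by every map
family, diagonal-Gaussian log-likelihoods, the sticky Chinese restaurant
process (sCRP) prior over contexts, and the particle filter that
approximates the sCRP's posterior predictive over a bounded label history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KalmanState",
    "SCRPParams",
    "ParticleSet",
    "kalman_gain",
    "gaussian_loglik",
    "scrp_prior",
    "particle_filter_step",
]

LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class KalmanState:
    """Uncertainty matrix Σ over a map's feature/state dimension.

    ``obs_noise_var`` is the observation noise σn² and ``init_var`` the
    initial per-dimension variance σ0² (Σ starts as σ0²·I).
    """

    Sigma: np.ndarray
    obs_noise_var: float = 1.0
    init_var: float = 1.6
    #: Diagonal process noise added before each measurement update. Zero by
    #: default (pure annealing: hᵀΣh is then non-increasing). A positive
    #: value models slowly drifting targets and keeps a steady-state gain,
    #: which is what lets a value map unlearn after a contingency change.
    process_noise: float = 0.0

    @classmethod
    def identity(
        cls,
        dim: int,
        init_var: float = 1.6,
        obs_noise_var: float = 1.0,
        process_noise: float = 0.0,
    ) -> "KalmanState":
        return cls(
            Sigma=init_var * np.eye(dim),
            obs_noise_var=obs_noise_var,
            init_var=init_var,
            process_noise=process_noise,
        )

    def gain(self, h: np.ndarray) -> np.ndarray:
        """Kalman gain k = Σh / (hᵀΣh + σn²) and in-place Σ update.

        With zero process noise the quadratic form hᵀΣh is non-increasing
        under repeated updates with the same h, so the gain anneals as
        confidence grows.
        """
        if not np.all(np.isfinite(h)):
            raise ValueError("non-finite h")
        if self.process_noise > 0 and np.any(h):
            self.Sigma[np.diag_indices_from(self.Sigma)] += self.process_noise
        Sh = self.Sigma @ h
        denom = float(h @ Sh) + self.obs_noise_var
        k = Sh / denom
        if np.any(h):
            self.Sigma -= np.outer(k, Sh)
            # Keep Σ numerically symmetric.
            self.Sigma = 0.5 * (self.Sigma + self.Sigma.T)
        return k

    def copy(self) -> "KalmanState":
        return KalmanState(self.Sigma.copy(), self.obs_noise_var, self.init_var, self.process_noise)


def kalman_gain(state: KalmanState, h: np.ndarray) -> tuple[np.ndarray, KalmanState]:
    """Functional wrapper: gain k = Σh/(hᵀΣh+σn²) and updated state.

    ``h = 0`` returns a zero gain and leaves Σ unchanged.
    """
    new = state.copy()
    k = new.gain(np.asarray(h, dtype=float))
    return k, new


def gaussian_loglik(residual: np.ndarray | float, variance: float) -> float:
    """Log-density of ``residual`` under independent N(0, variance) per dim.

    The covariance is diagonal with a shared variance, so the log-likelihood
    sums the univariate normal log-densities over dimensions.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    r = np.atleast_1d(np.asarray(residual, dtype=float))
    d = r.size
    return float(-0.5 * d * (LOG_2PI + math.log(variance)) - 0.5 * (r @ r) / variance)


@dataclass(frozen=True)
class SCRPParams:
    """Sticky-CRP hyperparameters.

    ``concentration`` (α) sets the prior mass on a brand-new context,
    ``stickiness`` (β) the extra mass on the immediately preceding context,
    ``history_window`` (y) how many past assignments the counts cover, and
    ``max_contexts`` (z_max) the cap on simultaneously tracked contexts.
    """

    concentration: float
    stickiness: float
    history_window: int = 10
    max_contexts: int = 10


def scrp_prior(
    counts: dict[int, int],
    prev_context: int | None,
    params: SCRPParams,
    n_known: int | None = None,
) -> np.ndarray:
    """Sticky-CRP probability vector over known contexts plus a "new" slot.

    Existing context z gets (N_z + β·[z == prev])/(α+β+y) and the new-context
    slot α/(α+β+y). When fewer than y observations exist the vector is
    renormalised so it remains a distribution (the relative weights are
    preserved). Counts for labels >= n_known (proto-contexts sampled by
    particles before any map was spawned) fold into the new slot.
    """
    if n_known is None:
        n_known = (max(counts) + 1) if counts else 0
        if prev_context is not None:
            n_known = max(n_known, prev_context + 1)
    denom = params.concentration + params.stickiness + params.history_window
    w = np.zeros(n_known + 1)
    for z, n_z in counts.items():
        idx = min(z, n_known)
        w[idx] += n_z
    w[n_known] += params.concentration
    if prev_context is not None:
        w[min(prev_context, n_known)] += params.stickiness
    w /= denom
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate sCRP weights")
    return w / total


class ParticleSet:
    """Particles approximating the sCRP posterior predictive.

    Each particle is a context-assignment history holding the last ``y``
    labels. Particles are refreshed by direct sampling from the current
    posterior at every step (no importance weights are carried); the hook
    ``advance`` may be overridden for a weighted variant.
    """

    def __init__(self, windows: np.ndarray, params: SCRPParams):
        self.windows = np.asarray(windows, dtype=np.int64)  # (n, <=y), -1 = empty
        self.params = params

    @classmethod
    def initialise(
        cls,
        n_particles: int,
        init_probs: np.ndarray,
        params: SCRPParams,
        rng: np.random.Generator,
    ) -> "ParticleSet":
        """Draw each particle's first label multinomially from ``init_probs``."""
        p = np.asarray(init_probs, dtype=float)
        p = p / p.sum()
        labels = rng.choice(len(p), size=n_particles, p=p)
        return cls(labels[:, None], params)

    @property
    def n_particles(self) -> int:
        return self.windows.shape[0]

    def advance(self, posterior: np.ndarray, rng: np.random.Generator) -> None:
        """Each particle samples its next label from ``posterior``.

        The posterior's last slot is "new": a particle drawing it records the
        label ``len(posterior) - 1`` (the index the next spawned context will
        take). Windows keep only the last y labels.
        """
        p = np.asarray(posterior, dtype=float)
        if not math.isclose(p.sum(), 1.0, rel_tol=1e-6):
            raise ValueError("posterior must be normalised")
        if len(p) - 1 >= self.params.max_contexts and p[-1] > 0:
            raise ValueError("posterior places mass on labels beyond max_contexts")
        labels = rng.choice(len(p), size=self.n_particles, p=p)
        y = self.params.history_window
        w = np.concatenate([self.windows, labels[:, None]], axis=1)
        if w.shape[1] > y:
            w = w[:, -y:]
        self.windows = w

    def prior_estimate(self, n_known: int) -> np.ndarray:
        """Average of scrp_prior over particles' counts and last labels."""
        n, width = self.windows.shape
        slots = n_known + 1
        lab = np.minimum(np.where(self.windows < 0, slots, self.windows), n_known)
        lab = np.where(self.windows < 0, -1, lab)
        w = np.zeros((n, slots))
        valid = lab >= 0
        flat = (lab + np.arange(n)[:, None] * slots)[valid]
        np.add.at(w.reshape(-1), flat, 1.0)
        prev = lab[:, -1]
        w[np.arange(n)[prev >= 0], prev[prev >= 0]] += self.params.stickiness
        w[:, n_known] += self.params.concentration
        w /= w.sum(axis=1, keepdims=True)
        return w.mean(axis=0)

    def copy(self) -> "ParticleSet":
        return ParticleSet(self.windows.copy(), self.params)


def particle_filter_step(
    particles: ParticleSet,
    posterior: np.ndarray,
    params: SCRPParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, ParticleSet]:
    """Advance the particle set one step and return the new prior estimate.

    Each particle samples its next context label from ``posterior``; the
    prior estimate is the particle average of the sCRP weights computed from
    each particle's (updated) window counts and last label.
    """
    new = particles.copy()
    new.params = params
    new.advance(posterior, rng)
    return new.prior_estimate(len(posterior) - 1), new
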