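"""Context-specific convolved-reward maps over locations.

The outcome stream sees only the location channel. It smooths the recent
reward sequence with a symmetric γ-decaying kernel to form a "convolved
reward" cr attributed to the location visited ``len`` steps ago, learns a
per-context map C of these diffuse local values, and evaluates context
likelihoods from the residual cr − C(s) under the Kalman-tracked
per-location variance.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .inference import gaussian_loglik

__all__ = [
    "ConvolvedRewardMap",
    "RewardBuffer",
    "build_kernel",
    "convolved_reward",
    "oi_update",
    "oi_loglik",
]


def build_kernel(gamma: float, flen: int) -> np.ndarray:
    """Symmetric decaying kernel with entry γ^|i| for offsets −len..len.

    A reward ``i`` steps away from the centre state contributes γ^|i| to the
    centre's diffuse value estimate, so the kernel spreads credit to the
    states visited just before and just after the reward.
    """
    if flen < 0:
        raise ValueError("filter length must be >= 0")
    if not (0 < gamma <= 1):
        raise ValueError("gamma must be in (0, 1]")
    offsets = np.arange(-flen, flen + 1)
    return gamma ** np.abs(offsets)


@dataclass
class ConvolvedRewardMap:
    """Diffuse state-value map C with per-location estimated variance.

    ``lr_weight`` (α_o) scales the Kalman gain into the effective learning
    rate; it is large so that outcome maps are learnt near-one-shot, and the
    effective rate is clipped to 1 so C stays a convex combination of
    observed convolved rewards.

    ``var`` is the per-location variance used for inference, estimated from
    the observed residuals (the Kalman innovation variance): the convolved
    reward at a location genuinely scatters with the path taken, so the
    parameter uncertainty alone — which anneals to zero — would make the
    likelihood arbitrarily over-confident. The annealing parameter variance
    ``kvar`` sets only the learning rate.
    """

    C: np.ndarray
    var: np.ndarray
    kvar: np.ndarray
    obs_noise_var: float = 1.0
    lr_weight: float = 23.0
    filter_len: int = 2
    var_floor: float = 1e-3

    @classmethod
    def fresh(
        cls,
        n_locations: int,
        init_var: float = 1.6,
        obs_noise_var: float = 1.0,
        lr_weight: float = 23.0,
        filter_len: int = 2,
    ) -> "ConvolvedRewardMap":
        return cls(
            C=np.zeros(n_locations),
            var=np.full(n_locations, float(init_var)),
            kvar=np.full(n_locations, float(init_var)),
            obs_noise_var=obs_noise_var,
            lr_weight=lr_weight,
            filter_len=filter_len,
        )

    def copy(self) -> "ConvolvedRewardMap":
        return ConvolvedRewardMap(
            self.C.copy(), self.var.copy(), self.kvar.copy(),
            self.obs_noise_var, self.lr_weight, self.filter_len, self.var_floor,
        )


class RewardBuffer:
    """Sliding window of (reward, location) pairs within the current trial.

    Holds the last 2·len+1 entries. The window persists across attempts
    within a trial (the teleport is instantaneous) and is cleared at trial
    boundaries. Inference is skipped until the window is full, giving the
    stated temporal delay of ``len`` states preceding inference.
    """

    def __init__(self, filter_len: int):
        self.filter_len = filter_len
        self.window: deque[tuple[float, int]] = deque(maxlen=2 * filter_len + 1)

    def append(self, reward: float, location: int) -> None:
        self.window.append((float(reward), int(location)))

    def clear(self) -> None:
        self.window.clear()

    @property
    def ready(self) -> bool:
        return len(self.window) == 2 * self.filter_len + 1

    def rewards(self) -> np.ndarray:
        return np.array([r for r, _ in self.window])

    def center_location(self) -> int:
        return self.window[self.filter_len][1]


def convolved_reward(buffer: RewardBuffer, kernel: np.ndarray) -> tuple[float, int] | None:
    """Kernel-weighted reward window and the location it estimates.

    Returns (cr, centre location) where the centre is the location visited
    ``len`` steps ago; returns None ("not ready") while the window is
    underfull, in which case no inference happens this step.
    """
    if not buffer.ready:
        return None
    cr = float(kernel @ buffer.rewards())
    return cr, buffer.center_location()


def oi_update(cmap: ConvolvedRewardMap, location: int, cr: float) -> ConvolvedRewardMap:
    """Move C(location) toward cr with rate α = clip(α_o·k(location), 0, 1).

    The Kalman step on the location's one-hot reduces to a scalar update of
    that location's quantities: k = σ²/(σ²+σn²) from the annealing parameter
    variance, which then shrinks as σ² ← σ² − kσ². The inference variance is
    updated toward the squared pre-update residual at the slower, unscaled
    rate k, so it tracks how reproducible cr actually is at this location
    rather than the last surprise. Other locations are untouched.
    """
    kv = cmap.kvar[location]
    k = kv / (kv + cmap.obs_noise_var)
    alpha = min(1.0, cmap.lr_weight * k)
    cmap.C[location] += alpha * (cr - cmap.C[location])
    # Residual after learning from this sample: early one-shot updates then
    # leave no residue (learning transients do not inflate the variance),
    # while genuine scatter the annealed map can no longer absorb does.
    resid_sq = (cr - cmap.C[location]) ** 2
    cmap.var[location] = max(
        cmap.var_floor, cmap.var[location] + k * (resid_sq - cmap.var[location])
    )
    cmap.kvar[location] = kv - k * kv
    return cmap


def oi_loglik(cmap: ConvolvedRewardMap, location: int, cr: float) -> float:
    """Gaussian log-likelihood of cr under this context's map at location."""
    return gaussian_loglik(cr - cmap.C[location], float(cmap.var[location]))
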