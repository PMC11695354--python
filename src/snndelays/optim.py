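"""Adam optimizer and learning-rate schedules for the manual BPTT engine.

Weights follow a one-cycle schedule (linear warm-up to a peak learning rate,
cosine decay to near zero); delays follow plain cosine annealing.  Both are
standard practice for training spiking networks with learnable delays.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Adam", "one_cycle_lr", "cosine_annealing_lr"]


class Adam:
    """Adam with per-parameter state kept in a dict keyed by parameter name.

    ``reset_entries(name, idx)`` zeroes the first/second-moment state of
    individual entries — used when a rewiring step reactivates a synapse, so
    the fresh connection does not inherit stale momentum.
    """

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t: dict[str, int] = {}

    def step(self, name: str, param: np.ndarray, grad: np.ndarray, lr: float) -> None:
        """Update ``param`` in place."""
        if name not in self.m:
            self.m[name] = np.zeros_like(param)
            self.v[name] = np.zeros_like(param)
            self.t[name] = 0
        self.t[name] += 1
        t = self.t[name]
        m = self.m[name]
        v = self.v[name]
        m *= self.beta1
        m += (1 - self.beta1) * grad
        v *= self.beta2
        v += (1 - self.beta2) * grad * grad
        mhat = m / (1 - self.beta1**t)
        vhat = v / (1 - self.beta2**t)
        param -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def reset_entries(self, name: str, flat_idx: np.ndarray) -> None:
        if name in self.m and flat_idx.size:
            self.m[name].flat[flat_idx] = 0.0
            self.v[name].flat[flat_idx] = 0.0


def one_cycle_lr(
    step: int,
    total_steps: int,
    max_lr: float,
    pct_start: float = 0.3,
    div_factor: float = 25.0,
    final_div_factor: float = 1e4,
) -> float:
    """One-cycle schedule: linear ramp to ``max_lr``, cosine decay to ~0."""
    if total_steps <= 1:
        return max_lr
    start_lr = max_lr / div_factor
    final_lr = start_lr / final_div_factor
    warm = max(1, int(round(pct_start * total_steps)))
    if step < warm:
        frac = step / warm
        return start_lr + frac * (max_lr - start_lr)
    frac = (step - warm) / max(1, total_steps - warm)
    return final_lr + 0.5 * (max_lr - final_lr) * (1 + math.cos(math.pi * min(frac, 1.0)))


def cosine_annealing_lr(step: int, total_steps: int, max_lr: float, min_lr: float = 0.0) -> float:
    """Cosine annealing from ``max_lr`` down to ``min_lr`` over ``total_steps``."""
    if total_steps <= 1:
        return max_lr
    frac = min(step / total_steps, 1.0)
    return min_lr + 0.5 * (max_lr - min_lr) * (1 + math.cos(math.pi * frac))
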