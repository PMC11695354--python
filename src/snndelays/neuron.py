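"""Leaky integrate-and-fire dynamics with a surrogate-gradient spike nonlinearity.

The membrane potential of neuron *i* evolves by a forward-Euler step

    u[t] = (1 - dt/tau) * u[t-1] * (1 - s[t-1]) + I[t] * dt
    s[t] = H(u[t] - theta)

where ``H`` is the Heaviside step.  The ``(1 - s[t-1])`` factor implements
reset-to-zero: the membrane stores the *pre-reset* value at each step and the
reset is applied when the value is carried over.  The Heaviside forward pass is
kept exact; its backward pass is replaced by an arctan-family surrogate so the
network is trainable with backpropagation through time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LIFParams",
    "LIFState",
    "lif_step",
    "surrogate_spike",
    "surrogate_derivative",
]


@dataclass(frozen=True)
class LIFParams:
    """Membrane constants of a leaky integrate-and-fire population.

    Parameters
    ----------
    tau
        Membrane time constant, in units of the integration step.
    dt
        Integration step.
    theta
        Firing threshold, in dimensionless membrane units.  A spike is
        emitted iff ``u >= theta`` (the boundary counts as a spike).
    surrogate_width
        Slope parameter of the surrogate derivative; larger means a
        narrower, taller pseudo-derivative around threshold.
    """

    tau: float = 10.05
    dt: float = 1.0
    theta: float = 1.0
    surrogate_width: float = 5.0

    def __post_init__(self) -> None:
        if not (self.tau > self.dt > 0):
            raise ValueError(f"require tau > dt > 0, got tau={self.tau}, dt={self.dt}")
        if not self.theta > 0:
            raise ValueError(f"firing threshold must be positive, got {self.theta}")
        decay = 1.0 - self.dt / self.tau
        if not (0.0 < decay < 1.0):
            raise ValueError(f"decay factor (1 - dt/tau) = {decay} outside (0, 1)")

    @property
    def decay(self) -> float:
        """Per-step membrane decay factor ``1 - dt/tau``."""
        return 1.0 - self.dt / self.tau


@dataclass
class LIFState:
    """Membrane potentials and spikes of one population at one time step."""

    u: np.ndarray
    s: np.ndarray

    @classmethod
    def zeros(cls, n: int, dtype=np.float64) -> "LIFState":
        return cls(u=np.zeros(n, dtype=dtype), s=np.zeros(n, dtype=dtype))


def lif_step(state: LIFState, input_current: np.ndarray, params: LIFParams) -> LIFState:
    """Advance a LIF population by one Euler step.

    Returns a fresh :class:`LIFState`; the input state is not modified.
    Deterministic and stateless: identical inputs give identical outputs.
    """
    input_current = np.asarray(input_current, dtype=float)
    if input_current.shape != state.u.shape:
        raise ValueError(
            f"input current shape {input_current.shape} does not match "
            f"membrane shape {state.u.shape}"
        )
    if not np.all(np.isfinite(input_current)):
        raise ValueError("input current contains non-finite values")
    u_new = params.decay * state.u * (1.0 - state.s) + input_current * params.dt
    s_new = surrogate_spike(u_new - params.theta)
    return LIFState(u=u_new, s=s_new)


def surrogate_spike(v: np.ndarray | float) -> np.ndarray:
    """Exact Heaviside forward pass of the spike nonlinearity.

    ``1`` iff ``v >= 0`` (membrane at threshold spikes).  The associated
    backward pass is :func:`surrogate_derivative`; the pairing is applied
    explicitly inside the BPTT engine since this package does not rely on an
    autodiff framework.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("pre-activation contains non-finite values")
    return (v >= 0.0).astype(float)


def surrogate_derivative(v: np.ndarray | float, width: float = 5.0) -> np.ndarray:
    """Arctan-family pseudo-derivative of the spike nonlinearity.

    d/dv [ (1/pi) * arctan(pi * width * v) ] = width / (1 + (pi * width * v)^2)

    Strictly positive, maximal at ``v = 0``, finite everywhere.
    """
    v = np.asarray(v, dtype=float)
    return width / (1.0 + (np.pi * width * v) ** 2)
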