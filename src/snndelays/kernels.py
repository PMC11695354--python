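"""Gaussian delay kernels and their causal convolution with spike trains.

Each synapse (j -> i) carries a weight ``w_ij`` and a continuous delay
``d_ij``.  The synapse is realised as a 1-D temporal kernel of length
``T_d + 1`` over lag indices ``n = 0..T_d``:

    k_ij[n] = w_ij * c_ij * exp( -1/2 * ((n - T_d + d_ij + 1) / sigma)^2 )

``c_ij`` normalises each kernel so that ``sum_n k_ij[n] = w_ij`` exactly:
the kernel redistributes the synaptic weight over time without changing its
total.  Index ``n = T_d`` corresponds to lag 0 (the current time step), so
the Gaussian bump is centred at lag ``d_ij + 1``: a spike at time ``t0``
produces a current that peaks at ``t0 + d + 1``.

The postsynaptic current is the strictly causal convolution

    I[t, i] = sum_j sum_{n=0}^{T_d} k_ij[n] * S_j[t - T_d + n]

with zero padding for negative times (silence before stimulus onset).

During training ``sigma`` is annealed from a broad initial value down to a
small one: broad kernels let gradients "see" far-away candidate delays;
narrow kernels sharpen each synapse into an effectively discrete delay line.

Backward-pass helpers (gradients of the convolution w.r.t. kernels, and of
kernels w.r.t. weights and delays) live here too, since this package
implements backpropagation through time explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DelayedSynapseLayer",
    "SigmaSchedule",
    "build_delay_kernels",
    "delayed_current",
    "anneal_sigma",
    "clamp_delays",
    "clamp_delay_values",
    "gaussian_kernel_profiles",
    "kernel_param_grads",
    "delayed_current_batch",
    "delayed_current_backward",
]

DEFAULT_T_D = 25
DEFAULT_SIGMA = 12.5


@dataclass
class DelayedSynapseLayer:
    """Paired weight and delay parameters for one all-to-all delayed layer.

    Parameters
    ----------
    weights
        ``(n_post, n_pre)`` real matrix of synaptic weights ``w_ij``.
    delays
        ``(n_post, n_pre)`` real matrix of synaptic delays ``d_ij`` in
        timesteps.  Continuous during training; kept in ``[0, T_d - 1]``.
    T_d
        Maximum delay in timesteps; the kernel has ``T_d + 1`` taps.
    sigma
        Standard deviation of the Gaussian kernel, in timesteps.
    """

    weights: np.ndarray
    delays: np.ndarray
    T_d: int = DEFAULT_T_D
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        if self.weights.shape != self.delays.shape:
            raise ValueError(
                f"weights shape {self.weights.shape} != delays shape {self.delays.shape}"
            )
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.T_d < 1:
            raise ValueError(f"T_d must be >= 1, got {self.T_d}")

    @property
    def n_post(self) -> int:
        return self.weights.shape[0]

    @property
    def n_pre(self) -> int:
        return self.weights.shape[1]


def gaussian_kernel_profiles(
    delays: np.ndarray, sigma: float, T_d: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised Gaussian lag profiles and intermediates for the backward pass.

    Returns ``(ghat, g, z)`` where ``ghat[..., n]`` sums to 1 over ``n``; the
    full kernel is ``w[..., None] * ghat``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    n = np.arange(T_d + 1, dtype=float)
    z = (n - T_d + np.asarray(delays, dtype=float)[..., None] + 1.0) / sigma
    g = np.exp(-0.5 * z * z)
    ghat = g / g.sum(axis=-1, keepdims=True)
    return ghat, g, z


def build_delay_kernels(layer: DelayedSynapseLayer) -> np.ndarray:
    """Kernel tensor ``(n_post, n_pre, T_d + 1)``; each kernel sums to its weight."""
    ghat, _, _ = gaussian_kernel_profiles(layer.delays, layer.sigma, layer.T_d)
    return layer.weights[..., None] * ghat


def kernel_param_grads(
    dk: np.ndarray,
    weights: np.ndarray,
    ghat: np.ndarray,
    g: np.ndarray,
    z: np.ndarray,
    sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Backprop ``dL/dk -> (dL/dw, dL/dd)`` through the normalised kernel.

    Uses dghat/dd = (dg/dd - ghat * sum dg/dd) / sum g with
    dg/dd = -g * z / sigma.
    """
    dw = np.sum(dk * ghat, axis=-1)
    dg_dd = -g * z / sigma
    G = g.sum(axis=-1, keepdims=True)
    dghat_dd = (dg_dd - ghat * dg_dd.sum(axis=-1, keepdims=True)) / G
    dd = weights * np.sum(dk * dghat_dd, axis=-1)
    return dw, dd


def _sliding_windows(spikes_btc: np.ndarray, n_taps: int) -> np.ndarray:
    """Left-pad along time and expose lag windows: ``(B, T, C) -> (B, T, C, n_taps)``.

    ``X[b, t, c, n] = S[b, t - (n_taps - 1) + n, c]`` with zeros for t < 0.
    """
    B, T, C = spikes_btc.shape
    pad = np.zeros((B, n_taps - 1, C), dtype=spikes_btc.dtype)
    padded = np.concatenate([pad, spikes_btc], axis=1)
    win = np.lib.stride_tricks.sliding_window_view(padded, n_taps, axis=1)
    return np.ascontiguousarray(win)  # (B, T, C, n_taps)


def delayed_current_batch(spikes_btc: np.ndarray, kernels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Causal delayed convolution for a batch.

    Parameters
    ----------
    spikes_btc
        ``(B, T, n_pre)`` presynaptic activity (binary spikes or analog frames).
    kernels
        ``(n_post, n_pre, T_d + 1)`` kernel tensor.

    Returns
    -------
    currents : ``(B, T, n_post)``
    windows : the lag-window tensor cached for the backward pass.
    """
    P, C, N = kernels.shape
    B, T, C_in = spikes_btc.shape
    if C_in != C:
        raise ValueError(f"spike channels {C_in} != kernel presynaptic size {C}")
    X = _sliding_windows(spikes_btc, N)  # (B, T, C, N)
    kflat = kernels.reshape(P, C * N)
    I = X.reshape(B * T, C * N) @ kflat.T
    return I.reshape(B, T, P), X


def delayed_current_backward(
    dI: np.ndarray,
    windows: np.ndarray,
    kernels: np.ndarray,
    need_input_grad: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Backprop through :func:`delayed_current_batch`.

    Returns ``(dL/dkernels, dL/dspikes)``; the latter is ``None`` when
    ``need_input_grad`` is false (e.g. for the input layer).
    """
    P, C, N = kernels.shape
    B, T, _, _ = windows.shape
    dkflat = dI.reshape(B * T, P).T @ windows.reshape(B * T, C * N)
    dk = dkflat.reshape(P, C, N)
    dS = None
    if need_input_grad:
        dSpad = np.zeros((B, T + N - 1, C))
        for n in range(N):
            dSpad[:, n : n + T, :] += dI @ kernels[:, :, n]
        dS = dSpad[:, N - 1 :, :]
    return dk, dS


def delayed_current(spikes: np.ndarray, layer: DelayedSynapseLayer) -> np.ndarray:
    """Postsynaptic currents ``(T, n_post)`` from a single spike train ``(T, n_pre)``.

    Strictly causal: ``I[t]`` depends only on spikes in ``{t - T_d, ..., t}``.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.ndim != 2:
        raise ValueError(f"expected (T, n_pre) spike array, got shape {spikes.shape}")
    if spikes.shape[1] != layer.n_pre:
        raise ValueError(
            f"spike train has {spikes.shape[1]} channels, layer expects {layer.n_pre}"
        )
    kernels = build_delay_kernels(layer)
    I, _ = delayed_current_batch(spikes[None, :, :], kernels)
    return I[0]


@dataclass(frozen=True)
class SigmaSchedule:
    """Annealing schedule for the kernel standard deviation.

    Linear decay from ``sigma_init`` to ``sigma_min`` over the first
    ``anneal_frac`` of training, constant at ``sigma_min`` afterwards.
    """

    sigma_init: float = DEFAULT_SIGMA
    sigma_min: float = 0.5
    anneal_frac: float = 0.75

    def __post_init__(self) -> None:
        if self.sigma_min <= 0:
            raise ValueError(f"sigma_min must be positive, got {self.sigma_min}")
        if self.sigma_init < self.sigma_min:
            raise ValueError("sigma_init must be >= sigma_min")
        if not (0.0 < self.anneal_frac <= 1.0):
            raise ValueError(f"anneal_frac must be in (0, 1], got {self.anneal_frac}")


def anneal_sigma(epoch: int, total_epochs: int, schedule: SigmaSchedule | None = None) -> float:
    """Kernel width at a given epoch; monotone non-increasing in ``epoch``."""
    if schedule is None:
        schedule = SigmaSchedule()
    if not (0 <= epoch <= total_epochs):
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs}]")
    if total_epochs == 0:
        return schedule.sigma_init
    knee = schedule.anneal_frac * total_epochs
    frac = min(epoch / knee, 1.0)
    return schedule.sigma_init + frac * (schedule.sigma_min - schedule.sigma_init)


def clamp_delay_values(delays: np.ndarray, T_d: int) -> np.ndarray:
    """Project delays into ``[0, T_d - 1]`` so the kernel peak stays in support."""
    return np.clip(delays, 0.0, float(T_d - 1))


def clamp_delays(layer: DelayedSynapseLayer) -> DelayedSynapseLayer:
    """Clamp a layer's delays in place into ``[0, T_d - 1]``; idempotent."""
    layer.delays = clamp_delay_values(layer.delays, layer.T_d)
    return layer
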