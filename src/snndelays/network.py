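"""Feed-forward spiking classifier with per-synapse learnable delays.

Architecture (one hidden layer):

    input (C channels x T steps)
      -> delayed convolution (Gaussian delay kernels)     [input layer]
      -> batch normalization (optional, per hidden channel)
      -> LIF population, unrolled over T steps
      -> dropout on hidden spike trains (training only)
      -> delayed convolution                              [output layer]
      -> non-spiking leaky readout integrators (threshold = infinity)
      -> logits  = sum over time of readout membrane voltage

Both layers can be trained in two connectivity regimes:

* dense / fixed-mask — a plain weight matrix, optionally masked by a fixed
  random sparsity pattern chosen at initialisation;
* dynamic sparse — a :class:`~snndelays.structure.SignedSparseParam`
  (``w = s * max(theta, 0)``) whose active set is rewired during training.

Because no autodiff framework is used, this module implements the backward
pass explicitly.  Gradients flow through the spike nonlinearity via the
arctan surrogate derivative; through the Gaussian kernels via analytic
kernel-shape derivatives (so delays receive gradients); and through time via
the standard reverse recursion over the membrane update.  The layer-level
building blocks are each validated against finite differences or
independent scalar oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import (
    SigmaSchedule,
    clamp_delay_values,
    delayed_current_backward,
    delayed_current_batch,
    gaussian_kernel_profiles,
    kernel_param_grads,
)
from .neuron import LIFParams, surrogate_derivative
from .structure import SignedSparseParam, effective_weights

__all__ = ["NetworkConfig", "SpikingDelayNet", "softmax_cross_entropy"]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters defining one network instance.

    ``learn_delays`` and ``learn_structure`` span the four-condition
    ablation grid: {fixed, learned} structure x {fixed, learned} delays.
    ``sparsity_level`` is the fraction of dormant synapses (0 = dense);
    with fixed structure the active mask is drawn once at random, and
    Dale's law is omitted (a bad fixed sign assignment cannot be escaped).
    """

    n_inputs: int = 40
    n_hidden: int = 256
    n_outputs: int = 20
    T: int = 80
    T_d: int = 25
    dropout_p: float = 0.4
    batch_norm: bool = True
    dale: bool = True
    learn_delays: bool = True
    learn_structure: bool = True
    sparsity_level: float = 0.0
    tau: float = 10.05
    theta: float = 1.0
    surrogate_width: float = 5.0
    readout: str = "voltage_sum"  # or "current_sum"
    weight_gain: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sparsity_level < 1.0):
            raise ValueError(f"sparsity_level must be in [0, 1), got {self.sparsity_level}")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError(f"dropout_p must be in [0, 1), got {self.dropout_p}")
        if self.readout not in ("voltage_sum", "current_sum"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.T <= self.T_d:
            raise ValueError("T must exceed T_d")

    @property
    def lif(self) -> LIFParams:
        return LIFParams(tau=self.tau, theta=self.theta, surrogate_width=self.surrogate_width)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    B = logits.shape[0]
    nll = -np.log(np.maximum(p[np.arange(B), labels], 1e-300))
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return float(nll.mean()), dlogits / B


class _Layer:
    """One delayed connection block: weights (dense-masked or sparse-signed)
    plus a delay matrix."""

    def __init__(
        self,
        n_post: int,
        n_pre: int,
        cfg: NetworkConfig,
        rng: np.random.Generator,
        name: str,
    ):
        self.name = name
        self.n_post, self.n_pre = n_post, n_pre
        n_total = n_post * n_pre
        budget = max(1, int(round((1.0 - cfg.sparsity_level) * n_total)))
        fan_in = max(1.0, (1.0 - cfg.sparsity_level) * n_pre)
        scale = cfg.weight_gain / np.sqrt(fan_in)
        if cfg.learn_structure:
            self.sparse: SignedSparseParam | None = SignedSparseParam.init_random(
                n_post, n_pre, budget, rng, dale=cfg.dale, theta_scale=scale
            )
            self.w = None
            self.mask = None
        else:
            self.sparse = None
            self.w = rng.normal(0.0, scale, size=(n_post, n_pre))
            mask = np.zeros(n_total)
            mask[rng.permutation(n_total)[:budget]] = 1.0
            self.mask = mask.reshape(n_post, n_pre)
            self.w *= self.mask
        self.delays = rng.uniform(0.0, cfg.T_d - 1.0, size=(n_post, n_pre))

    def weights(self) -> np.ndarray:
        if self.sparse is not None:
            return effective_weights(self.sparse)
        return self.w * self.mask


class SpikingDelayNet:
    """The classifier; holds parameters, current kernel width, and the
    forward/backward machinery.  All randomness is drawn from generators
    passed in explicitly, so runs are reproducible end to end."""

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.sigma = SigmaSchedule().sigma_init
        self.layer1 = _Layer(cfg.n_hidden, cfg.n_inputs, cfg, rng, "layer1")
        self.layer2 = _Layer(cfg.n_outputs, cfg.n_hidden, cfg, rng, "layer2")
        self.gamma = np.ones(cfg.n_hidden)
        self.beta = np.zeros(cfg.n_hidden)
        self.bn_mean = np.zeros(cfg.n_hidden)
        self.bn_var = np.ones(cfg.n_hidden)

    # ------------------------------------------------------------------ forward

    def _readout_coeffs(self) -> np.ndarray:
        # Normalised by T (and by the integrator gain tau for the voltage
        # readout) so logits start O(1) and the softmax is not saturated at
        # initialisation; a constant rescale of all logits, so argmax and
        # the readout's temporal weighting are unchanged.
        T = self.cfg.T
        if self.cfg.readout == "current_sum":
            return np.ones(T) / T
        a = self.cfg.lif.decay
        t = np.arange(T)
        return (1.0 - a ** (T - t)) / (1.0 - a) / (T * self.cfg.tau)

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Run the network on a batch ``x`` of shape (samples, channels, time).

        Returns ``(logits, cache)``; the cache holds every intermediate the
        backward pass needs.  Deterministic in eval mode.
        """
        cfg = self.cfg
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[1] != cfg.n_inputs or x.shape[2] != cfg.T:
            raise ValueError(
                f"expected batch of shape (B, {cfg.n_inputs}, {cfg.T}), got {x.shape}"
            )
        if training and cfg.dropout_p > 0 and rng is None:
            raise ValueError("training-mode forward with dropout needs an rng")
        xb = np.transpose(x, (0, 2, 1))  # (B, T, C)
        B, T, _ = xb.shape
        cache: dict = {"training": training}

        # input delayed convolution
        w1 = self.layer1.weights()
        ghat1, g1, z1 = gaussian_kernel_profiles(self.layer1.delays, self.sigma, cfg.T_d)
        k1 = w1[..., None] * ghat1
        I1, win1 = delayed_current_batch(xb, k1)
        cache.update(w1=w1, ghat1=ghat1, g1=g1, z1=z1, k1=k1, win1=win1)

        # batch normalization over (batch, time) per hidden channel
        if cfg.batch_norm:
            if training:
                mu = I1.mean(axis=(0, 1))
                var = I1.var(axis=(0, 1))
                self.bn_mean = (1 - self.BN_MOMENTUM) * self.bn_mean + self.BN_MOMENTUM * mu
                self.bn_var = (1 - self.BN_MOMENTUM) * self.bn_var + self.BN_MOMENTUM * var
            else:
                mu, var = self.bn_mean, self.bn_var
            xhat = (I1 - mu) / np.sqrt(var + self.BN_EPS)
            Ih = self.gamma * xhat + self.beta
            cache.update(bn_xhat=xhat, bn_var=var)
        else:
            Ih = I1

        # LIF hidden population, unrolled over time
        lif = cfg.lif
        a = lif.decay
        u = np.zeros((B, cfg.n_hidden))
        s = np.zeros((B, cfg.n_hidden))
        U = np.empty((B, T, cfg.n_hidden))
        S = np.empty((B, T, cfg.n_hidden))
        for t in range(T):
            u = a * u * (1.0 - s) + Ih[:, t, :] * lif.dt
            s = (u >= lif.theta).astype(float)
            U[:, t, :] = u
            S[:, t, :] = s
        cache.update(U=U, S=S)

        # dropout on hidden spike trains
        if training and cfg.dropout_p > 0:
            keep = 1.0 - cfg.dropout_p
            mask = (rng.random(S.shape) < keep) / keep
            Sd = S * mask
            cache["dropout_mask"] = mask
        else:
            Sd = S
            cache["dropout_mask"] = None
        cache["Sd"] = Sd

        # output delayed convolution + leaky readout
        w2 = self.layer2.weights()
        ghat2, g2, z2 = gaussian_kernel_profiles(self.layer2.delays, self.sigma, cfg.T_d)
        k2 = w2[..., None] * ghat2
        I2, win2 = delayed_current_batch(Sd, k2)
        coeffs = self._readout_coeffs()
        logits = np.einsum("bto,t->bo", I2, coeffs)
        cache.update(w2=w2, ghat2=ghat2, g2=g2, z2=z2, k2=k2, win2=win2, coeffs=coeffs)
        return logits, cache

    # ----------------------------------------------------------------- backward

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate through time; returns gradients keyed by parameter.

        Weight gradients are reported as ``dL/dw`` for dense layers and as
        the straight-through ``dL/dtheta = s * dL/dw`` for sparse-signed
        layers (exact on active entries; on dormant entries it is the
        gradient the magnitude would see if marginally active, which is what
        gradient-guided regrowth ranks).
        """
        cfg = self.cfg
        lif = cfg.lif
        a = lif.decay
        grads: dict[str, np.ndarray] = {}

        # readout -> output-layer currents
        dI2 = dlogits[:, None, :] * cache["coeffs"][None, :, None]
        dk2, dSd = delayed_current_backward(dI2, cache["win2"], cache["k2"])
        dw2, dd2 = kernel_param_grads(
            dk2, cache["w2"], cache["ghat2"], cache["g2"], cache["z2"], self.sigma
        )
        grads.update(self._weight_grad(self.layer2, dw2, "2"))
        grads["d2"] = dd2

        # dropout
        if cache["dropout_mask"] is not None:
            dS = dSd * cache["dropout_mask"]
        else:
            dS = dSd

        # LIF reverse recursion.  u[t+1] = a*u[t]*(1-s[t]) + Ih[t+1];
        # s[t] = H(u[t] - theta) with surrogate derivative.
        U, S = cache["U"], cache["S"]
        B, T, H = S.shape
        dIh = np.empty((B, T, H))
        lam_next = np.zeros((B, H))  # dL/du[t+1]
        for t in range(T - 1, -1, -1):
            ds = dS[:, t, :].copy()
            if t < T - 1:
                ds -= lam_next * a * U[:, t, :]
            lam = ds * surrogate_derivative(U[:, t, :] - lif.theta, lif.surrogate_width)
            if t < T - 1:
                lam += lam_next * a * (1.0 - S[:, t, :])
            dIh[:, t, :] = lam * lif.dt
            lam_next = lam

        # batch norm backward (training statistics)
        if cfg.batch_norm:
            xhat = cache["bn_xhat"]
            var = cache["bn_var"]
            grads["gamma"] = np.sum(dIh * xhat, axis=(0, 1))
            grads["beta"] = np.sum(dIh, axis=(0, 1))
            if cache["training"]:
                m = xhat.shape[0] * xhat.shape[1]
                dxhat = dIh * self.gamma
                dI1 = (
                    dxhat
                    - dxhat.mean(axis=(0, 1))
                    - xhat * (dxhat * xhat).mean(axis=(0, 1))
                ) / np.sqrt(var + self.BN_EPS)
            else:
                dI1 = dIh * self.gamma / np.sqrt(var + self.BN_EPS)
        else:
            dI1 = dIh

        # input layer
        dk1, _ = delayed_current_backward(dI1, cache["win1"], cache["k1"], need_input_grad=False)
        dw1, dd1 = kernel_param_grads(
            dk1, cache["w1"], cache["ghat1"], cache["g1"], cache["z1"], self.sigma
        )
        grads.update(self._weight_grad(self.layer1, dw1, "1"))
        grads["d1"] = dd1
        return grads

    @staticmethod
    def _weight_grad(layer: _Layer, dw: np.ndarray, suffix: str) -> dict[str, np.ndarray]:
        if layer.sparse is not None:
            return {f"theta{suffix}": layer.sparse.signs * dw}
        return {f"w{suffix}": dw * layer.mask}

    # ---------------------------------------------------------------- utilities

    def clamp_delays(self) -> None:
        self.layer1.delays = clamp_delay_values(self.layer1.delays, self.cfg.T_d)
        self.layer2.delays = clamp_delay_values(self.layer2.delays, self.cfg.T_d)

    def state_dict(self) -> dict[str, np.ndarray]:
        """Flat array snapshot of all parameters (checkpoint format)."""
        out: dict[str, np.ndarray] = {
            "d1": self.layer1.delays.copy(),
            "d2": self.layer2.delays.copy(),
            "gamma": self.gamma.copy(),
            "beta": self.beta.copy(),
            "bn_mean": self.bn_mean.copy(),
            "bn_var": self.bn_var.copy(),
            "sigma": np.array(self.sigma),
        }
        for layer, sfx in ((self.layer1, "1"), (self.layer2, "2")):
            if layer.sparse is not None:
                out[f"signs{sfx}"] = layer.sparse.signs.copy()
                out[f"theta{sfx}"] = layer.sparse.theta.copy()
                out[f"budget{sfx}"] = np.array(layer.sparse.budget)
            else:
                out[f"w{sfx}"] = layer.w.copy()
                out[f"mask{sfx}"] = layer.mask.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.layer1.delays = np.array(state["d1"])
        self.layer2.delays = np.array(state["d2"])
        self.gamma = np.array(state["gamma"])
        self.beta = np.array(state["beta"])
        self.bn_mean = np.array(state["bn_mean"])
        self.bn_var = np.array(state["bn_var"])
        self.sigma = float(state["sigma"])
        for layer, sfx in ((self.layer1, "1"), (self.layer2, "2")):
            if f"theta{sfx}" in state:
                layer.sparse = SignedSparseParam(
                    signs=np.array(state[f"signs{sfx}"]),
                    theta=np.array(state[f"theta{sfx}"]),
                    budget=int(state[f"budget{sfx}"]),
                )
                layer.w = None
                layer.mask = None
            else:
                layer.sparse = None
                layer.w = np.array(state[f"w{sfx}"])
                layer.mask = np.array(state[f"mask{sfx}"])
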