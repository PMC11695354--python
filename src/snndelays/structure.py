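"""Dynamic sparse rewiring under Dale's-law sign constraints.

Connectivity is reparameterised per layer as

    w_ij = s_ij * max(theta_ij, 0)

with a sign matrix ``s`` fixed at creation and a trainable magnitude
``theta``.  A connection with ``theta <= 0`` is *dormant* and contributes
exactly zero weight.  Training drops connections implicitly whenever the
optimizer (helped by L1 regularization) pushes a magnitude non-positive;
a rewiring step then restores the fixed synapse budget by reactivating
dormant connections, either at random or — following the gradient-guided
regrowth idea — by picking the dormant entries whose loss gradient most
strongly wants them active.  Under the positive-magnitude parameterisation
only *negative* dL/dtheta argues for activation, so growth selects the k
strongest negative gradients among dormant entries.

Dale's law (each presynaptic neuron is exclusively excitatory or
inhibitory) is imposed structurally: one random sign per presynaptic
neuron, broadcast down its outgoing column, so it can never be violated by
training or rewiring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SignedSparseParam",
    "RewirePolicy",
    "RewireLog",
    "make_sign_matrix",
    "effective_weights",
    "l1_penalty",
    "rewire_step",
    "sparsity",
]


def make_sign_matrix(
    n_post: int, n_pre: int, dale: bool, rng: np.random.Generator
) -> np.ndarray:
    """Random ``(n_post, n_pre)`` matrix of +-1 synaptic signs.

    With ``dale=True``, one sign is drawn per presynaptic neuron and
    broadcast down its outgoing column, so every connection leaving neuron
    ``j`` shares sign ``s_j``.  With ``dale=False`` signs are i.i.d.
    Deterministic given the generator state.
    """
    if n_post < 1 or n_pre < 1:
        raise ValueError("sign matrix dimensions must be >= 1")
    if dale:
        col = rng.choice([-1.0, 1.0], size=n_pre)
        return np.broadcast_to(col, (n_post, n_pre)).copy()
    return rng.choice([-1.0, 1.0], size=(n_post, n_pre))


@dataclass
class SignedSparseParam:
    """Sign-constrained sparse parameter: fixed signs, trainable magnitudes.

    ``budget`` is the number of simultaneously active synapses the rewiring
    rule conserves.  The active mask is derived, never stored:
    ``theta > 0``.
    """

    signs: np.ndarray
    theta: np.ndarray
    budget: int

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.signs.shape != self.theta.shape:
            raise ValueError("signs and theta must have the same shape")
        if not np.all(np.abs(self.signs) == 1.0):
            raise ValueError("signs must be +-1")
        if not (0 < self.budget <= self.theta.size):
            raise ValueError(f"budget {self.budget} outside (0, {self.theta.size}]")
        self.signs.setflags(write=False)

    @property
    def active_mask(self) -> np.ndarray:
        return self.theta > 0.0

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.active_mask))

    @classmethod
    def init_random(
        cls,
        n_post: int,
        n_pre: int,
        budget: int,
        rng: np.random.Generator,
        dale: bool = True,
        theta_scale: float | None = None,
    ) -> "SignedSparseParam":
        """Fresh parameter with ``budget`` random active synapses.

        Active magnitudes are drawn half-normal with scale
        ``theta_scale`` (default ``1/sqrt(n_pre)``); the rest start dormant
        at a small negative value.
        """
        if theta_scale is None:
            theta_scale = 1.0 / np.sqrt(n_pre)
        signs = make_sign_matrix(n_post, n_pre, dale, rng)
        theta = np.full((n_post, n_pre), -theta_scale * 0.1)
        flat = rng.permutation(n_post * n_pre)[:budget]
        theta.flat[flat] = np.abs(rng.normal(0.0, theta_scale, size=budget))
        theta.flat[flat] = np.maximum(theta.flat[flat], 1e-6)
        return cls(signs=signs, theta=theta, budget=budget)


@dataclass(frozen=True)
class RewirePolicy:
    """How dropped synapses are replaced.

    grow_mode
        ``"gradient"`` — activate the k dormant entries with the most
        negative dL/dtheta (gradient-guided regrowth); ``"random"`` —
        activate k uniformly random dormant entries.
    theta_init
        Magnitude assigned to reactivated synapses (small and positive:
        active immediately, cheap to re-prune).
    resample_delay
        Whether a reactivated synapse draws a fresh random delay (delay
        selection through structure learning).
    cadence
        Rewiring frequency in training iterations.
    average_grads
        Rank dormant entries by the gradient averaged over the iterations
        since the last rewiring event instead of the instantaneous
        minibatch gradient — a lower-variance regrowth signal, useful with
        ``cadence > 1``.
    """

    grow_mode: str = "gradient"
    theta_init: float = 1e-3
    resample_delay: bool = True
    cadence: int = 1
    average_grads: bool = False

    def __post_init__(self) -> None:
        if self.grow_mode not in ("gradient", "random"):
            raise ValueError(f"unknown grow_mode {self.grow_mode!r}")
        if self.theta_init <= 0:
            raise ValueError("theta_init must be positive")
        if self.cadence < 1:
            raise ValueError("cadence must be >= 1")


@dataclass
class RewireLog:
    """Index sets touched by one rewiring step (flat indices)."""

    grown: np.ndarray
    n_dormant_before: int

    @property
    def n_grown(self) -> int:
        return int(self.grown.size)


def effective_weights(param: SignedSparseParam) -> np.ndarray:
    """``w = s * max(theta, 0)``; dormant entries are exactly zero."""
    return param.signs * np.maximum(param.theta, 0.0)


def l1_penalty(param: SignedSparseParam, lam: float) -> float:
    """L1 magnitude penalty over active entries: ``lam * sum max(theta, 0)``.

    Its gradient is a constant ``+lam`` on every active magnitude — a steady
    push toward dormancy that encourages pruning of unhelpful synapses.
    """
    if lam < 0:
        raise ValueError("L1 coefficient must be non-negative")
    return float(lam * np.sum(np.maximum(param.theta, 0.0)))


def sparsity(param: SignedSparseParam) -> float:
    """Fraction of potential synapses currently dormant."""
    return 1.0 - param.n_active / param.theta.size


def rewire_step(
    param: SignedSparseParam,
    grads: np.ndarray,
    policy: RewirePolicy,
    rng: np.random.Generator,
) -> tuple[SignedSparseParam, RewireLog]:
    """Restore the synapse budget after the optimizer dropped connections.

    Call after the optimizer update: entries newly at ``theta <= 0`` are
    dormant; ``k = budget - active count`` dormant entries are reactivated
    at ``policy.theta_init``.  In ``"gradient"`` mode the k dormant entries
    with the most negative ``dL/dtheta`` are chosen (ties broken by the
    smallest flat index; if fewer than k dormant entries have a negative
    gradient, the remainder are filled at random).  The sign matrix is
    never touched.  Mutates ``param.theta`` in place and returns it with a
    log of grown indices.
    """
    grads = np.asarray(grads, dtype=float)
    if grads.shape != param.theta.shape:
        raise ValueError(
            f"gradient shape {grads.shape} != theta shape {param.theta.shape}"
        )
    dormant = ~param.active_mask
    n_dormant = int(np.count_nonzero(dormant))
    k = param.budget - param.n_active
    if k < 0:
        raise ValueError("active count exceeds budget; rewiring cannot drop")
    if k > n_dormant:
        raise ValueError(
            f"budget infeasible: need to grow {k} but only {n_dormant} dormant entries"
        )
    if k == 0:
        return param, RewireLog(grown=np.empty(0, dtype=int), n_dormant_before=n_dormant)

    dormant_flat = np.flatnonzero(dormant)
    if policy.grow_mode == "gradient":
        g = grads.flat[dormant_flat]
        neg = dormant_flat[g < 0]
        gneg = grads.flat[neg]
        if neg.size >= k:
            # ascending stable sort: most negative first, smallest flat index on ties
            order = np.argsort(gneg, kind="stable")
            chosen = neg[order[:k]]
        else:
            rest_pool = np.setdiff1d(dormant_flat, neg, assume_unique=True)
            extra = rng.choice(rest_pool, size=k - neg.size, replace=False)
            chosen = np.concatenate([neg, extra])
    else:
        chosen = rng.choice(dormant_flat, size=k, replace=False)

    param.theta.flat[chosen] = policy.theta_init
    return param, RewireLog(grown=np.sort(chosen), n_dormant_before=n_dormant)
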