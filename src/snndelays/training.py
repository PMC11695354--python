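"""Training loops: BPTT with surrogate gradients, delay-kernel annealing,
dynamic rewiring, and the four-condition ablation harness.

``train`` optimizes cross-entropy (plus an L1 magnitude penalty when the
structure is learned) with Adam, a one-cycle schedule on the weight
learning rate, and cosine annealing on the delay learning rate.  The kernel
width sigma is annealed per epoch; delays are clamped into their support
after every step.  When structure is learned, connections whose magnitude
the optimizer pushed non-positive become dormant and the synapse budget is
restored by a rewiring step each iteration.

``fit_delay_layer`` trains a single delayed layer by mean-squared error
against target currents — the planted-delay recovery setting.

``run_ablation`` trains the grid {fixed, learned structure} x {fixed,
learned delays} across sparsity levels, several seeds each; fixed-
connectivity conditions omit the Dale's-law sign constraint (a poor fixed
sign assignment could never be escaped).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kernels import (
    DelayedSynapseLayer,
    SigmaSchedule,
    anneal_sigma,
    clamp_delay_values,
    delayed_current_backward,
    delayed_current_batch,
    gaussian_kernel_profiles,
    kernel_param_grads,
)
from .network import NetworkConfig, SpikingDelayNet, softmax_cross_entropy
from .optim import Adam, cosine_annealing_lr, one_cycle_lr
from .structure import RewirePolicy, rewire_step, sparsity
from .synthetic import ClassPatternTask, PlantedDelayTask

__all__ = ["TrainConfig", "train", "evaluate", "fit_delay_layer", "run_ablation"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one training run."""

    epochs: int = 30
    batch_size: int = 128
    lr_weights: float = 0.01
    lr_delays: float = 0.1
    l1_lambda: float = 1e-5
    l1_lambda_input: float | None = None  # input layer override; None = l1_lambda
    seed: int = 0
    n_repeats: int = 3
    sigma_schedule: SigmaSchedule = field(default_factory=SigmaSchedule)
    rewire: RewirePolicy = field(default_factory=RewirePolicy)

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def evaluate(model: SpikingDelayNet, X: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
    """Classification accuracy in eval mode (dropout off, running BN stats)."""
    correct = 0
    for start in range(0, X.shape[0], batch_size):
        logits, _ = model.forward(X[start : start + batch_size], training=False)
        correct += int(np.sum(logits.argmax(axis=1) == y[start : start + batch_size]))
    return correct / X.shape[0]


def _resolve_dataset(dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(dataset, ClassPatternTask):
        (Xtr, ytr), (Xte, yte) = dataset.train, dataset.test
    else:
        Xtr, ytr = dataset
        Xte, yte = Xtr, ytr
    return Xtr, ytr, Xte, yte


def train(
    model: SpikingDelayNet,
    dataset,
    tcfg: TrainConfig,
) -> tuple[SpikingDelayNet, pd.DataFrame]:
    """Train a classifier; returns the model and a per-epoch metric history.

    ``dataset`` is a :class:`~snndelays.synthetic.ClassPatternTask` (its
    train/test split is used) or a plain ``(inputs, labels)`` tuple.
    Fully deterministic given ``tcfg.seed``.
    """
    cfg = model.cfg
    Xtr, ytr, Xte, yte = _resolve_dataset(dataset)
    rng = np.random.default_rng(tcfg.seed)
    opt = Adam()
    n_train = Xtr.shape[0]
    steps_per_epoch = max(1, n_train // tcfg.batch_size)
    total_steps = tcfg.epochs * steps_per_epoch
    history = []
    gstep = 0
    grad_accum: dict = {}

    for epoch in range(tcfg.epochs):
        model.sigma = anneal_sigma(epoch, tcfg.epochs, tcfg.sigma_schedule)
        order = rng.permutation(n_train)
        epoch_loss, epoch_correct, epoch_count = 0.0, 0, 0
        for b in range(steps_per_epoch):
            idx = order[b * tcfg.batch_size : (b + 1) * tcfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits, cache = model.forward(xb, training=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if cfg.learn_structure:
                lam1 = tcfg.l1_lambda if tcfg.l1_lambda_input is None else tcfg.l1_lambda_input
                for layer, lam in ((model.layer1, lam1), (model.layer2, tcfg.l1_lambda)):
                    loss += lam * float(np.sum(np.maximum(layer.sparse.theta, 0.0)))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, step {b}; "
                    "lower the learning rates or weight gain"
                )
            grads = model.backward(cache, dlogits)

            lr_w = one_cycle_lr(gstep, total_steps, tcfg.lr_weights)
            lr_d = cosine_annealing_lr(gstep, total_steps, tcfg.lr_delays)
            _apply_updates(model, grads, opt, lr_w, lr_d, tcfg, rng, grad_accum)
            gstep += 1

            epoch_loss += loss * len(idx)
            epoch_correct += int(np.sum(logits.argmax(axis=1) == yb))
            epoch_count += len(idx)

        row = {
            "epoch": epoch,
            "loss": epoch_loss / epoch_count,
            "train_acc": epoch_correct / epoch_count,
            "test_acc": evaluate(model, Xte, yte),
            "sigma": model.sigma,
        }
        if cfg.learn_structure:
            row["sparsity"] = sparsity(model.layer1.sparse)
        else:
            row["sparsity"] = cfg.sparsity_level
        history.append(row)
    return model, pd.DataFrame(history)


def _apply_updates(
    model: SpikingDelayNet,
    grads: dict[str, np.ndarray],
    opt: Adam,
    lr_w: float,
    lr_d: float,
    tcfg: TrainConfig,
    rng: np.random.Generator,
    grad_accum: dict,
) -> None:
    cfg = model.cfg
    lam1 = tcfg.l1_lambda if tcfg.l1_lambda_input is None else tcfg.l1_lambda_input
    for layer, sfx, lam in ((model.layer1, "1", lam1), (model.layer2, "2", tcfg.l1_lambda)):
        if layer.sparse is not None:
            g = grads[f"theta{sfx}"].copy()
            active = layer.sparse.active_mask
            g[active] += lam  # d/dtheta of lam * sum max(theta, 0)
            g[~active] = 0.0  # dormant magnitudes are frozen (DEEP R)
            opt.step(f"theta{sfx}", layer.sparse.theta, g, lr_w)
            if tcfg.rewire.average_grads:
                acc = grad_accum.setdefault(sfx, [np.zeros_like(g), 0])
                acc[0] += grads[f"theta{sfx}"]
                acc[1] += 1
            if opt.t[f"theta{sfx}"] % tcfg.rewire.cadence == 0:
                if tcfg.rewire.average_grads:
                    acc = grad_accum[sfx]
                    grow_signal = acc[0] / acc[1]
                    acc[0][:] = 0.0
                    acc[1] = 0
                else:
                    grow_signal = grads[f"theta{sfx}"]
                _, log = rewire_step(layer.sparse, grow_signal, tcfg.rewire, rng)
                if log.n_grown:
                    opt.reset_entries(f"theta{sfx}", log.grown)
                    opt.reset_entries(f"d{sfx}", log.grown)
                    if tcfg.rewire.resample_delay and not cfg.learn_delays:
                        layer.delays.flat[log.grown] = rng.uniform(
                            0.0, cfg.T_d - 1.0, size=log.n_grown
                        )
        else:
            opt.step(f"w{sfx}", layer.w, grads[f"w{sfx}"], lr_w)
            layer.w *= layer.mask
        if cfg.learn_delays:
            opt.step(f"d{sfx}", layer.delays, grads[f"d{sfx}"], lr_d)
    if cfg.batch_norm:
        opt.step("gamma", model.gamma, grads["gamma"], lr_w)
        opt.step("beta", model.beta, grads["beta"], lr_w)
    model.clamp_delays()


# --------------------------------------------------------------- planted delays


def fit_delay_layer(
    task: PlantedDelayTask,
    epochs: int = 60,
    batch_size: int = 256,
    lr_weights: float = 0.05,
    lr_delays: float = 0.3,
    seed: int = 0,
    sigma_schedule: SigmaSchedule | None = None,
) -> tuple[DelayedSynapseLayer, pd.DataFrame]:
    """Fit one delayed layer to planted-delay targets by mean-squared error.

    Weights start small and random, delays uniform; sigma is annealed so
    the delay gradient first sees a broad basin and then sharpens.  Returns
    the fitted layer and a per-epoch loss history.
    """
    if sigma_schedule is None:
        sigma_schedule = SigmaSchedule()
    rng = np.random.default_rng(seed)
    n_samples, n_pre, T = task.inputs.shape
    n_post = task.true_delays.shape[0]
    T_d = task.T_d
    w = rng.normal(0.0, 0.1, size=(n_post, n_pre))
    d = rng.uniform(0.0, T_d - 1.0, size=(n_post, n_pre))
    X = np.transpose(task.inputs, (0, 2, 1))  # (B, T, C)
    Y = np.transpose(task.targets, (0, 2, 1))
    opt = Adam()
    steps_per_epoch = max(1, n_samples // batch_size)
    total_steps = epochs * steps_per_epoch
    history = []
    gstep = 0
    sigma = sigma_schedule.sigma_init
    for epoch in range(epochs):
        sigma = anneal_sigma(epoch, epochs, sigma_schedule)
        order = rng.permutation(n_samples)
        epoch_loss = 0.0
        for b in range(steps_per_epoch):
            idx = order[b * batch_size : (b + 1) * batch_size]
            xb, yb = X[idx], Y[idx]
            ghat, g, z = gaussian_kernel_profiles(d, sigma, T_d)
            k = w[..., None] * ghat
            I, win = delayed_current_batch(xb, k)
            err = I - yb
            loss = 0.5 * float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            dI = err / err.size
            dk, _ = delayed_current_backward(dI, win, k, need_input_grad=False)
            dw, dd = kernel_param_grads(dk, w, ghat, g, z, sigma)
            opt.step("w", w, dw, one_cycle_lr(gstep, total_steps, lr_weights))
            opt.step("d", d, dd, cosine_annealing_lr(gstep, total_steps, lr_delays))
            d = clamp_delay_values(d, T_d)
            gstep += 1
            epoch_loss += loss
        history.append({"epoch": epoch, "loss": epoch_loss / steps_per_epoch, "sigma": sigma})
    layer = DelayedSynapseLayer(weights=w, delays=d, T_d=T_d, sigma=sigma)
    return layer, pd.DataFrame(history)


def delay_recovery_fraction(layer: DelayedSynapseLayer, task: PlantedDelayTask, tol: float = 1.0) -> float:
    """Fraction of synapses whose learned delay is within ``tol`` steps of the planted one."""
    return float(np.mean(np.abs(layer.delays - task.true_delays) <= tol))


# -------------------------------------------------------------------- ablation

ABLATION_CONDITIONS = [
    ("learned", "learned"),
    ("learned", "fixed"),
    ("fixed", "learned"),
    ("fixed", "fixed"),
]


def run_ablation(
    base_cfg: NetworkConfig,
    dataset: ClassPatternTask,
    sparsity_levels: list[float],
    tcfg: TrainConfig,
    keep_models: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Train the 2x2 {structure, delays} grid at each sparsity level.

    Each condition runs ``tcfg.n_repeats`` seeds (derived as
    ``tcfg.seed + repeat``).  Fixed-connectivity conditions omit Dale's
    law.  Returns a tidy results table (one row per condition x level x
    repeat) and, when ``keep_models`` is set, the trained models plus their
    untrained initial parameter snapshots keyed by
    ``(structure, delays, level, repeat)``.
    """
    if not sparsity_levels:
        raise ValueError("sparsity_levels must be nonempty")
    rows = []
    models: dict = {}
    for level in sparsity_levels:
        for structure, delays in ABLATION_CONDITIONS:
            learn_structure = structure == "learned"
            for rep in range(tcfg.n_repeats):
                seed = tcfg.seed + rep
                cfg = replace(
                    base_cfg,
                    learn_structure=learn_structure,
                    learn_delays=delays == "learned",
                    sparsity_level=level,
                    dale=base_cfg.dale and learn_structure,
                )
                model = SpikingDelayNet(cfg, np.random.default_rng(seed))
                init_state = model.state_dict()
                model, hist = train(model, dataset, replace(tcfg, seed=seed))
                rows.append(
                    {
                        "structure": structure,
                        "delays": delays,
                        "sparsity": level,
                        "repeat": rep,
                        "seed": seed,
                        "train_acc": hist["train_acc"].iloc[-1],
                        "test_acc": hist["test_acc"].iloc[-1],
                    }
                )
                if keep_models:
                    models[(structure, delays, level, rep)] = (init_state, model)
    return pd.DataFrame(rows), models
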