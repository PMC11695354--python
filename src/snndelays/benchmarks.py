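"""Canned desk-scale experiments exercising each mechanism end to end.

These are the package's reference experiments: small enough to run in
minutes on one CPU, large enough that each mechanism (delay learning,
dynamic pruning, receptive-field organisation) has room to express itself.
Each function is a pure function of its seed and returns a plain dict of
measured quantities.

Problem sizes (the package's own choices, see the methods note):

* delay recovery — one delayed layer, 20 presynaptic x 5 postsynaptic
  channels, T = 100, 2,000 Bernoulli(0.1) spike rasters;
* structure recovery — 24 channels (6 informative), 6 classes, 720
  samples, hidden size 32 at 87.5% sparsity, 120 epochs;
* ablation / autocorrelation shift — 16 channels x 40 steps, 10 classes,
  800 samples, hidden size 64, the 2x2 {structure, delays} grid at 87.5%
  sparsity, 3 seeds each, 60 epochs.
"""

from __future__ import annotations

import numpy as np

from .kernels import SigmaSchedule
from .network import NetworkConfig, SpikingDelayNet
from .receptive_fields import all_receptive_fields
from .spatial import compare_morans_distributions, max_permuted_morans, queen_weights
from .structure import RewirePolicy
from .synthetic import (
    ClassPatternConfig,
    make_class_pattern_task,
    make_planted_delay_task,
    make_planted_structure_task,
)
from .training import TrainConfig, delay_recovery_fraction, fit_delay_layer, run_ablation, train

__all__ = [
    "delay_recovery_benchmark",
    "structure_recovery_benchmark",
    "ablation_benchmark",
    "input_precision",
]


def delay_recovery_benchmark(seed: int = 0, n_samples: int = 2000) -> dict:
    """Train a single delayed layer on a planted-delay task and score recovery.

    Returns the fraction of planted delays recovered within +-1 timestep,
    plus the training-loss ratio (final / initial).
    """
    task = make_planted_delay_task(
        n_pre=20, n_post=5, T=100, n_samples=n_samples, rate=0.1,
        rng=np.random.default_rng(seed),
    )
    layer, hist = fit_delay_layer(task, seed=seed)
    return {
        "recovery_frac": delay_recovery_fraction(layer, task),
        "loss_ratio": float(hist["loss"].iloc[-1] / hist["loss"].iloc[0]),
        "n_synapses": int(task.true_delays.size),
    }


def input_precision(model: SpikingDelayNet, task) -> float:
    """Fraction of active input synapses that target informative channels."""
    inf = task.informative_channels
    w = model.layer1.weights()
    per_channel = (w != 0).sum(axis=0)
    return float(per_channel[inf].sum() / per_channel.sum())


def structure_recovery_benchmark(seed: int = 0, epochs: int = 120) -> dict:
    """Dynamic pruning at 87.5% sparsity on a planted-structure task.

    Measures how strongly the surviving input synapses concentrate on the
    informative channel subset, relative to the chance rate (the
    informative fraction).
    """
    cfg = ClassPatternConfig(
        n_channels=24, T=40, n_classes=6, n_samples=720, n_features=6,
        T_d=12, noise_rate=0.03, informative_fraction=0.25,
    )
    task = make_planted_structure_task(cfg, np.random.default_rng(seed))
    net = NetworkConfig(
        n_inputs=24, n_hidden=32, n_outputs=6, T=40, T_d=12,
        dropout_p=0.0, batch_norm=True, dale=True,
        learn_structure=True, learn_delays=True, sparsity_level=0.875,
    )
    tcfg = TrainConfig(
        epochs=epochs, batch_size=90, lr_weights=0.1, lr_delays=0.1,
        l1_lambda=1e-3, seed=seed,
        sigma_schedule=SigmaSchedule(6.0, 0.5, 0.75),
        rewire=RewirePolicy(cadence=8, average_grads=True, theta_init=0.1),
    )
    model = SpikingDelayNet(net, np.random.default_rng(seed))
    model, hist = train(model, task, tcfg)
    precision = input_precision(model, task)
    chance = task.informative_channels.size / cfg.n_channels
    return {
        "precision": precision,
        "chance": chance,
        "precision_ratio": precision / chance,
        "test_acc": float(hist["test_acc"].iloc[-1]),
    }


def ablation_benchmark(
    seed: int = 0,
    n_repeats: int = 3,
    epochs: int = 60,
    n_perm: int = 2000,
    sparsity: float = 0.875,
) -> dict:
    """The 2x2 {structure, delays} grid at high sparsity, plus the
    trained-vs-untrained receptive-field autocorrelation comparison.

    The Moran's I comparison uses the learned-structure + learned-delays
    models: for each repeat, the permutation-maximized Moran's I of every
    output class's receptive field, trained vs. the untrained initial
    state of the same network.
    """
    cfg = ClassPatternConfig(
        n_channels=16, T=40, n_classes=10, n_samples=800, n_features=6,
        T_d=12, noise_rate=0.04,
    )
    task = make_class_pattern_task(cfg, np.random.default_rng(seed))
    base = NetworkConfig(
        n_inputs=16, n_hidden=64, n_outputs=10, T=40, T_d=12,
        dropout_p=0.0, batch_norm=True, dale=True, sparsity_level=sparsity,
    )
    tcfg = TrainConfig(
        epochs=epochs, batch_size=100, lr_weights=0.1, lr_delays=0.1,
        l1_lambda=1e-4, seed=seed, n_repeats=n_repeats,
        sigma_schedule=SigmaSchedule(6.0, 0.5, 0.75),
    )
    table, models = run_ablation(base, task, [sparsity], tcfg, keep_models=True)

    by_structure = table.groupby("structure")["test_acc"].mean()
    trained_vals, untrained_vals = [], []
    weights = None
    for rep in range(n_repeats):
        init_state, model = models[("learned", "learned", sparsity, rep)]
        ref = SpikingDelayNet(model.cfg, np.random.default_rng(seed + rep))
        ref.load_state_dict(init_state)
        for m, bag in ((model, trained_vals), (ref, untrained_vals)):
            for rf in all_receptive_fields(m):
                if weights is None:
                    weights = queen_weights(*rf.matrix.shape)
                res = max_permuted_morans(
                    rf.matrix, weights, n_perm=n_perm, rng=seed + 1000 * rep + rf.class_id
                )
                bag.append(res.i_max_permuted)
    U, p = compare_morans_distributions(np.array(trained_vals), np.array(untrained_vals))
    return {
        "table": table,
        "learned_structure_acc": float(by_structure["learned"]),
        "fixed_structure_acc": float(by_structure["fixed"]),
        "moran_trained_mean": float(np.mean(trained_vals)),
        "moran_untrained_mean": float(np.mean(untrained_vals)),
        "moran_trained": trained_vals,
        "moran_untrained": untrained_vals,
        "mannwhitney_u": U,
        "p_value": p,
    }
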