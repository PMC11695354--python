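"""Synthetic spatio-temporal tasks with the statistical structure the model assumes.

Three generators:

* planted-delay tasks — spike rasters paired with target currents produced
  by a known (weight, delay) matrix, for testing whether gradient descent
  on Gaussian delay kernels recovers the planted delays;
* class-pattern tasks — multi-class spike rasters in which each class is a
  template of (channel, lag) features riding on background noise, shaped
  like the 40-channel x 80-step spectrogram classification problems the
  architecture targets; class identity is decodable only by combining
  features at distinct lags, which forces temporal coincidence detection;
* planted-structure tasks — class-pattern tasks in which only a designated
  channel subset is informative, for scoring whether dynamic pruning
  concentrates synapses on the channels that matter.

All generators are pure functions of (config, generator); targets in the
planted-delay task are computed by a direct shift-and-sum loop, independent
of the package's convolution machinery, so they can serve as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlantedDelayTask",
    "ClassPatternConfig",
    "ClassPatternTask",
    "make_planted_delay_task",
    "make_class_pattern_task",
    "make_planted_structure_task",
    "matched_filter_predict",
    "matched_filter_accuracy",
]


@dataclass
class PlantedDelayTask:
    """Spike rasters with currents generated by known weights and delays.

    ``targets[b, i, t] = sum_j true_weights[i, j] * inputs[b, j, t - (true_delays[i, j] + 1)]``
    (a one-hot delay line of lag ``d + 1``, matching the kernel convention
    that a parameter ``d`` peaks ``d + 1`` steps after the spike).
    """

    true_delays: np.ndarray  # (n_post, n_pre) int
    true_weights: np.ndarray  # (n_post, n_pre)
    inputs: np.ndarray  # (n_samples, n_pre, T)
    targets: np.ndarray  # (n_samples, n_post, T)
    T_d: int
    rate: float
    seed_info: dict = field(default_factory=dict)


def make_planted_delay_task(
    n_pre: int,
    n_post: int,
    T: int,
    n_samples: int,
    rate: float,
    rng: np.random.Generator,
    T_d: int = 25,
    dale: bool = False,
) -> PlantedDelayTask:
    """Generate a planted-delay regression task.

    Delays uniform on ``[0, T_d - 1]``; weight magnitudes uniform on
    ``[0.5, 1.5]`` with random signs (one sign per presynaptic channel when
    ``dale`` is set).  Fully determined by the generator state.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"spike rate must be in [0, 1), got {rate}")
    if T <= T_d:
        raise ValueError(f"T={T} must exceed T_d={T_d}")
    delays = rng.integers(0, T_d, size=(n_post, n_pre))
    mags = rng.uniform(0.5, 1.5, size=(n_post, n_pre))
    if dale:
        signs = np.broadcast_to(rng.choice([-1.0, 1.0], size=n_pre), (n_post, n_pre))
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_post, n_pre))
    weights = mags * signs
    inputs = (rng.random((n_samples, n_pre, T)) < rate).astype(float)

    # independent shift-and-sum oracle (no kernel machinery involved)
    targets = np.zeros((n_samples, n_post, T))
    for i in range(n_post):
        for j in range(n_pre):
            lag = int(delays[i, j]) + 1
            targets[:, i, lag:] += weights[i, j] * inputs[:, j, : T - lag]
    return PlantedDelayTask(
        true_delays=delays,
        true_weights=weights,
        inputs=inputs,
        targets=targets,
        T_d=T_d,
        rate=rate,
    )


@dataclass(frozen=True)
class ClassPatternConfig:
    """Generative settings for the class-pattern task.

    Each class template is ``n_features`` (channel, lag) pairs with lags in
    ``[0, T_d]``; each sample places one spike per feature at a random
    global onset, over Bernoulli background noise.
    """

    n_channels: int = 40
    T: int = 80
    n_classes: int = 10
    n_samples: int = 1000
    n_features: int = 8
    T_d: int = 25
    burst_len: int = 2
    noise_rate: float = 0.04
    test_fraction: float = 0.25
    informative_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.T_d + self.burst_len >= self.T:
            raise ValueError(
                f"template lags (up to T_d={self.T_d}) plus burst_len={self.burst_len} "
                f"must fit inside T={self.T}"
            )
        if self.burst_len < 1:
            raise ValueError("burst_len must be >= 1")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must be in [0, 1)")
        if not (0.0 < self.informative_fraction <= 1.0):
            raise ValueError("informative_fraction must be in (0, 1]")


@dataclass
class ClassPatternTask:
    """Labelled spike rasters built from class templates plus noise."""

    inputs: np.ndarray  # (n_samples, n_channels, T)
    labels: np.ndarray  # (n_samples,)
    templates: list  # per class: (channels array, lags array)
    idx_train: np.ndarray
    idx_test: np.ndarray
    config: ClassPatternConfig
    informative_channels: np.ndarray | None = None

    @property
    def train(self) -> tuple[np.ndarray, np.ndarray]:
        return self.inputs[self.idx_train], self.labels[self.idx_train]

    @property
    def test(self) -> tuple[np.ndarray, np.ndarray]:
        return self.inputs[self.idx_test], self.labels[self.idx_test]


def make_class_pattern_task(
    cfg: ClassPatternConfig, rng: np.random.Generator
) -> ClassPatternTask:
    """Generate a balanced multi-class spatio-temporal pattern task."""
    informative = np.arange(cfg.n_channels)
    return _make_pattern_task(cfg, rng, informative)


def make_planted_structure_task(
    cfg: ClassPatternConfig, rng: np.random.Generator
) -> ClassPatternTask:
    """Class-pattern task whose templates live on a designated channel subset.

    The remaining channels carry label-independent noise at a rate matched
    to the informative channels' average rate, so mean activity alone does
    not reveal the informative set.
    """
    n_inf = max(1, int(round(cfg.informative_fraction * cfg.n_channels)))
    informative = np.sort(rng.choice(cfg.n_channels, size=n_inf, replace=False))
    return _make_pattern_task(cfg, rng, informative)


def _make_pattern_task(
    cfg: ClassPatternConfig, rng: np.random.Generator, informative: np.ndarray
) -> ClassPatternTask:
    n_inf = informative.size
    templates = []
    for _ in range(cfg.n_classes):
        k = min(cfg.n_features, n_inf)
        channels = informative[rng.choice(n_inf, size=k, replace=False)]
        lags = rng.integers(0, cfg.T_d + 1, size=k)
        templates.append((channels, lags))

    # balanced labels, shuffled
    base = np.repeat(np.arange(cfg.n_classes), cfg.n_samples // cfg.n_classes)
    extra = rng.permutation(cfg.n_classes)[: cfg.n_samples - base.size]
    labels = rng.permutation(np.concatenate([base, extra]))

    # matched-rate noise: noise channels receive the template-induced extra rate
    extra_rate = cfg.n_features * cfg.burst_len / max(1, n_inf) / cfg.T
    noise_ch_rate = min(0.95, cfg.noise_rate + extra_rate)
    rates = np.full(cfg.n_channels, cfg.noise_rate)
    if n_inf < cfg.n_channels:
        noise_mask = np.ones(cfg.n_channels, dtype=bool)
        noise_mask[informative] = False
        rates[noise_mask] = noise_ch_rate

    inputs = (rng.random((cfg.n_samples, cfg.n_channels, cfg.T)) < rates[None, :, None]).astype(float)
    max_onset = cfg.T - cfg.T_d - cfg.burst_len
    onsets = rng.integers(0, max_onset + 1, size=cfg.n_samples)
    for b in range(cfg.n_samples):
        channels, lags = templates[labels[b]]
        for off in range(cfg.burst_len):
            inputs[b, channels, onsets[b] + lags + off] = 1.0

    perm = rng.permutation(cfg.n_samples)
    n_test = int(round(cfg.test_fraction * cfg.n_samples))
    idx_test, idx_train = perm[:n_test], perm[n_test:]
    return ClassPatternTask(
        inputs=inputs,
        labels=labels,
        templates=templates,
        idx_train=idx_train,
        idx_test=idx_test,
        config=cfg,
        informative_channels=None if n_inf == cfg.n_channels else informative,
    )


def matched_filter_predict(task: ClassPatternTask, X: np.ndarray) -> np.ndarray:
    """Oracle classifier: best template-correlation score over all onsets.

    Knows the true templates; used to bound how decodable a generated task
    is, independently of any trained network.
    """
    cfg = task.config
    max_onset = cfg.T - cfg.T_d - cfg.burst_len
    scores = np.zeros((X.shape[0], cfg.n_classes))
    for c, (channels, lags) in enumerate(task.templates):
        best = np.full(X.shape[0], -np.inf)
        for t0 in range(max_onset + 1):
            s = np.zeros(X.shape[0])
            for off in range(cfg.burst_len):
                s += X[:, channels, t0 + lags + off].sum(axis=1)
            best = np.maximum(best, s)
        scores[:, c] = best
    return scores.argmax(axis=1)


def matched_filter_accuracy(task: ClassPatternTask, subset: str = "test") -> float:
    """Accuracy of the matched-filter oracle on the train or test split."""
    X, y = task.test if subset == "test" else task.train
    return float(np.mean(matched_filter_predict(task, X) == y))
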