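"""Synthetic task generators: oracles, balance, decodability, purity."""

import numpy as np
import pytest
from numpy.testing import assert_allclose, assert_array_equal

from snndelays.kernels import DelayedSynapseLayer, delayed_current
from snndelays.synthetic import (
    ClassPatternConfig,
    make_class_pattern_task,
    make_planted_delay_task,
    make_planted_structure_task,
    matched_filter_accuracy,
    matched_filter_predict,
)


class TestPlantedDelayTask:
    def test_deterministic_given_seed(self):
        a = make_planted_delay_task(6, 3, 50, 20, 0.1, np.random.default_rng(4))
        b = make_planted_delay_task(6, 3, 50, 20, 0.1, np.random.default_rng(4))
        assert_array_equal(a.inputs, b.inputs)
        assert_array_equal(a.targets, b.targets)
        assert_array_equal(a.true_delays, b.true_delays)

    def test_zero_rate_all_zero(self):
        t = make_planted_delay_task(4, 2, 40, 10, 0.0, np.random.default_rng(0))
        assert t.inputs.sum() == 0 and t.targets.sum() == 0

    def test_targets_match_onehot_shift_definition(self, rng):
        """target[i, t] = sum_j w_ij S_j[t - (d_ij + 1)] — checked by an
        independent per-entry loop."""
        t = make_planted_delay_task(5, 3, 45, 4, 0.15, rng)
        for b in range(4):
            for i in range(3):
                for tt in range(45):
                    acc = sum(
                        t.true_weights[i, j] * t.inputs[b, j, tt - (t.true_delays[i, j] + 1)]
                        if tt - (t.true_delays[i, j] + 1) >= 0
                        else 0.0
                        for j in range(5)
                    )
                    assert t.targets[b, i, tt] == pytest.approx(acc, abs=1e-12)

    def test_targets_equal_tiny_sigma_kernel_convolution(self, rng):
        """The delayed-convolution machinery with near-zero sigma reproduces
        the independent shift-and-sum targets."""
        t = make_planted_delay_task(6, 4, 50, 3, 0.12, rng)
        layer = DelayedSynapseLayer(
            weights=t.true_weights, delays=t.true_delays.astype(float),
            T_d=t.T_d, sigma=1e-3,
        )
        for b in range(3):
            out = delayed_current(t.inputs[b].T, layer)  # (T, post)
            assert_allclose(out, t.targets[b].T, atol=1e-10)

    def test_dale_mode_column_signs(self):
        t = make_planted_delay_task(8, 5, 40, 2, 0.1, np.random.default_rng(2), dale=True)
        for j in range(8):
            assert len(np.unique(np.sign(t.true_weights[:, j]))) == 1

    def test_invalid_rate_raises(self):
        with pytest.raises(ValueError):
            make_planted_delay_task(4, 2, 40, 5, 1.5, np.random.default_rng(0))


class TestClassPatternTask:
    def test_noiseless_task_perfectly_decodable(self):
        cfg = ClassPatternConfig(
            n_channels=12, T=40, n_classes=4, n_samples=80, n_features=5,
            T_d=10, noise_rate=0.0,
        )
        task = make_class_pattern_task(cfg, np.random.default_rng(1))
        pred = matched_filter_predict(task, task.inputs)
        assert np.mean(pred == task.labels) == 1.0

    def test_label_balance(self):
        cfg = ClassPatternConfig(n_channels=10, T=40, n_classes=7, n_samples=100, T_d=10)
        task = make_class_pattern_task(cfg, np.random.default_rng(2))
        counts = np.bincount(task.labels, minlength=7)
        assert counts.max() - counts.min() <= 1

    def test_matched_filter_oracle_strong_at_default_noise(self):
        cfg = ClassPatternConfig(n_channels=16, T=40, n_classes=8, n_samples=400,
                                 n_features=6, T_d=12, noise_rate=0.04)
        task = make_class_pattern_task(cfg, np.random.default_rng(7))
        assert matched_filter_accuracy(task) > 0.95

    def test_split_partitions_samples(self):
        cfg = ClassPatternConfig(n_channels=8, T=30, n_classes=2, n_samples=60, T_d=8)
        task = make_class_pattern_task(cfg, np.random.default_rng(3))
        joined = np.sort(np.concatenate([task.idx_train, task.idx_test]))
        assert_array_equal(joined, np.arange(60))

    def test_lag_overflow_raises(self):
        with pytest.raises(ValueError):
            ClassPatternConfig(n_channels=8, T=20, n_classes=2, T_d=25)


class TestPlantedStructureTask:
    CFG = dict(
        n_channels=20, T=40, n_classes=4, n_samples=400, n_features=5,
        T_d=10, noise_rate=0.03, informative_fraction=0.25,
    )

    def test_informative_subset_recorded(self):
        task = make_planted_structure_task(
            ClassPatternConfig(**self.CFG), np.random.default_rng(5)
        )
        assert task.informative_channels is not None
        assert task.informative_channels.size == 5
        for channels, _ in task.templates:
            assert set(channels).issubset(set(task.informative_channels))

    def test_fraction_one_reduces_to_class_pattern(self):
        cfg = dict(self.CFG, informative_fraction=1.0)
        task = make_planted_structure_task(ClassPatternConfig(**cfg), np.random.default_rng(5))
        assert task.informative_channels is None

    def test_noise_channels_uninformative(self):
        """Per-class mean activity of noise channels is flat (plug-in MI ~ 0)."""
        task = make_planted_structure_task(
            ClassPatternConfig(**self.CFG), np.random.default_rng(6)
        )
        noise_ch = np.setdiff1d(np.arange(20), task.informative_channels)
        counts = task.inputs[:, noise_ch, :].sum(axis=(1, 2))
        # spike-count distributions per label: plug-in MI between label and
        # binned count should be near zero
        bins = np.quantile(counts, [0.25, 0.5, 0.75])
        binned = np.digitize(counts, bins)
        joint = np.zeros((4, 4))
        for lab, b in zip(task.labels, binned):
            joint[lab, b] += 1
        joint /= joint.sum()
        pi, pj = joint.sum(1, keepdims=True), joint.sum(0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            mi = np.nansum(joint * np.log(joint / (pi * pj)))
        assert mi < 0.02  # nats; ~chi-square noise floor for 400 samples

    def test_permuting_noise_channels_preserves_decodability(self):
        task = make_planted_structure_task(
            ClassPatternConfig(**self.CFG), np.random.default_rng(8)
        )
        rng = np.random.default_rng(0)
        noise_ch = np.setdiff1d(np.arange(20), task.informative_channels)
        X = task.inputs.copy()
        X[:, noise_ch, :] = X[:, rng.permutation(noise_ch), :]
        acc0 = np.mean(matched_filter_predict(task, task.inputs) == task.labels)
        acc1 = np.mean(matched_filter_predict(task, X) == task.labels)
        assert acc1 == pytest.approx(acc0, abs=0.02)
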