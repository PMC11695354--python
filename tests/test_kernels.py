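"""Gaussian delay kernels, causal delayed convolution, and sigma annealing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_allclose

from snndelays.kernels import (
    DelayedSynapseLayer,
    SigmaSchedule,
    anneal_sigma,
    build_delay_kernels,
    clamp_delay_values,
    clamp_delays,
    delayed_current,
)


def naive_delayed_current(spikes, kernels):
    """Triple-loop oracle for I[t, i] = sum_j sum_n k[i,j,n] S_j[t - T_d + n]."""
    T, n_pre = spikes.shape
    n_post, _, n_taps = kernels.shape
    T_d = n_taps - 1
    out = np.zeros((T, n_post))
    for t in range(T):
        for i in range(n_post):
            acc = 0.0
            for j in range(n_pre):
                for n in range(n_taps):
                    src = t - T_d + n
                    if src >= 0:
                        acc += kernels[i, j, n] * spikes[src, j]
            out[t, i] = acc
    return out


class TestKernels:
    def test_zero_delay_peak_and_sum(self):
        layer = DelayedSynapseLayer(weights=np.ones((1, 1)), delays=np.zeros((1, 1)))
        k = build_delay_kernels(layer)[0, 0]
        assert k.argmax() == 24  # centre n = T_d - d - 1
        assert_allclose(k.sum(), 1.0, rtol=1e-12)

    def test_negative_weight_sum(self, rng):
        layer = DelayedSynapseLayer(
            weights=np.full((1, 1), -2.0), delays=rng.uniform(0, 24, (1, 1))
        )
        assert_allclose(build_delay_kernels(layer).sum(), -2.0, rtol=1e-12)

    def test_tiny_sigma_one_hot(self):
        layer = DelayedSynapseLayer(
            weights=np.ones((1, 1)), delays=np.full((1, 1), 5.0), sigma=0.01
        )
        k = build_delay_kernels(layer)[0, 0]
        assert k.argmax() == 19  # T_d - d - 1 = 25 - 5 - 1
        assert k[19] > 0.999

    def test_kernel_sum_conservation_random(self, rng):
        """Normalization contract: every kernel sums to its weight."""
        n = 1000
        w = rng.uniform(-5, 5, n)
        d = rng.uniform(0, 24, n)
        sig = rng.uniform(0.3, 12.5, n)
        for wi, di, si in zip(w[:50], d[:50], sig[:50]):
            layer = DelayedSynapseLayer(weights=np.array([[wi]]), delays=np.array([[di]]), sigma=si)
            k = build_delay_kernels(layer)
            assert abs(k.sum() - wi) < 1e-6 * max(1.0, abs(wi))
        # the rest in one batched layer per sigma decile (same contract)
        for q in range(10):
            sel = slice(50 + q * 95, 50 + (q + 1) * 95)
            layer = DelayedSynapseLayer(
                weights=w[sel][None, :], delays=d[sel][None, :], sigma=float(sig[sel].mean())
            )
            k = build_delay_kernels(layer)
            assert np.all(np.abs(k.sum(-1) - w[sel]) < 1e-6 * np.maximum(1.0, np.abs(w[sel])))

    @given(d=st.floats(0, 23.9))
    @settings(max_examples=50, deadline=None)
    def test_peak_location_small_sigma(self, d):
        from hypothesis import assume

        # half-integer delays sit exactly between two bins: ambiguous peak
        assume(abs((d % 1.0) - 0.5) > 0.01)
        layer = DelayedSynapseLayer(
            weights=np.ones((1, 1)), delays=np.full((1, 1), d), sigma=0.05
        )
        k = build_delay_kernels(layer)[0, 0]
        assert k.argmax() == round(25 - d - 1)

    def test_sigma_nonpositive_raises(self):
        with pytest.raises(ValueError, match="sigma"):
            DelayedSynapseLayer(weights=np.ones((1, 1)), delays=np.zeros((1, 1)), sigma=0.0)


class TestDelayedCurrent:
    def test_matches_naive_oracle(self, rng):
        layer = DelayedSynapseLayer(
            weights=rng.normal(size=(10, 4)),
            delays=rng.uniform(0, 24, (10, 4)),
            sigma=rng.uniform(0.5, 10.0),
        )
        spikes = (rng.random((30, 4)) < 0.3).astype(float)
        expected = naive_delayed_current(spikes, build_delay_kernels(layer))
        assert_allclose(delayed_current(spikes, layer), expected, atol=1e-10)

    def test_single_spike_peak_time(self):
        d = 7
        layer = DelayedSynapseLayer(
            weights=np.ones((1, 1)), delays=np.full((1, 1), float(d)), sigma=0.01
        )
        spikes = np.zeros((40, 1))
        t0 = 5
        spikes[t0, 0] = 1.0
        out = delayed_current(spikes, layer)
        assert out[:, 0].argmax() == t0 + d + 1

    def test_zero_input_zero_output(self, rng):
        layer = DelayedSynapseLayer(
            weights=rng.normal(size=(3, 2)), delays=rng.uniform(0, 24, (3, 2))
        )
        assert_allclose(delayed_current(np.zeros((35, 2)), layer), 0.0)

    def test_linearity_over_channels(self, rng):
        layer = DelayedSynapseLayer(
            weights=rng.normal(size=(4, 2)), delays=rng.uniform(0, 24, (4, 2)), sigma=2.0
        )
        s = (rng.random((40, 2)) < 0.3).astype(float)
        only0 = s.copy(); only0[:, 1] = 0
        only1 = s.copy(); only1[:, 0] = 0
        assert_allclose(
            delayed_current(s, layer),
            delayed_current(only0, layer) + delayed_current(only1, layer),
            atol=1e-12,
        )

    def test_translation_equivariance(self, rng):
        layer = DelayedSynapseLayer(
            weights=rng.normal(size=(3, 2)), delays=rng.uniform(0, 20, (3, 2)), sigma=1.5
        )
        T, shift = 60, 9
        s = np.zeros((T, 2))
        s[20:25] = (rng.random((5, 2)) < 0.5).astype(float)
        shifted = np.roll(s, shift, axis=0)
        out = delayed_current(s, layer)
        out_shifted = delayed_current(shifted, layer)
        assert_allclose(out_shifted[30 + shift : 40 + shift], out[30:40], atol=1e-12)

    def test_causality(self, rng):
        """I[t] must not respond to spikes after t."""
        layer = DelayedSynapseLayer(
            weights=rng.normal(size=(2, 1)), delays=rng.uniform(0, 24, (2, 1)), sigma=3.0
        )
        s = np.zeros((50, 1)); s[30, 0] = 1.0
        out = delayed_current(s, layer)
        assert_allclose(out[:30], 0.0, atol=1e-15)

    def test_shape_mismatch_raises(self, rng):
        layer = DelayedSynapseLayer(weights=np.ones((2, 3)), delays=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="channels"):
            delayed_current(np.zeros((10, 4)), layer)


class TestSigmaSchedule:
    def test_endpoints_and_midpoint(self):
        sched = SigmaSchedule(sigma_init=12.5, sigma_min=0.5, anneal_frac=0.75)
        assert anneal_sigma(0, 100, sched) == 12.5
        assert anneal_sigma(100, 100, sched) == 0.5
        # linear interpolation inside the decay segment
        knee = 75
        expected = 12.5 + (30 / knee) * (0.5 - 12.5)
        assert_allclose(anneal_sigma(30, 100, sched), expected)

    def test_monotone_nonincreasing_random_configs(self, rng):
        for _ in range(100):
            init = rng.uniform(1, 20)
            sched = SigmaSchedule(
                sigma_init=init,
                sigma_min=rng.uniform(0.1, init),
                anneal_frac=rng.uniform(0.1, 1.0),
            )
            total = int(rng.integers(2, 60))
            vals = [anneal_sigma(e, total, sched) for e in range(total + 1)]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_invalid_sigma_min_raises(self):
        with pytest.raises(ValueError):
            SigmaSchedule(sigma_min=0.0)


class TestClampDelays:
    @pytest.mark.parametrize("d,expected", [(-0.3, 0.0), (30.0, 24.0), (12.7, 12.7)])
    def test_projection(self, d, expected):
        assert clamp_delay_values(np.array(d), 25) == expected

    def test_idempotent(self, rng):
        layer = DelayedSynapseLayer(
            weights=np.ones((3, 3)), delays=rng.uniform(-10, 40, (3, 3))
        )
        clamp_delays(layer)
        once = layer.delays.copy()
        clamp_delays(layer)
        assert_allclose(layer.delays, once)
        assert np.all(layer.delays >= 0) and np.all(layer.delays <= 24)
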