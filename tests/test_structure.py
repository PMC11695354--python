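"""Sign-constrained sparse parameters, rewiring, and Dale's-law invariants."""

import numpy as np
import pytest
from numpy.testing import assert_allclose, assert_array_equal

from snndelays.structure import (
    RewirePolicy,
    SignedSparseParam,
    effective_weights,
    l1_penalty,
    make_sign_matrix,
    rewire_step,
    sparsity,
)


class TestSignMatrix:
    def test_dale_columns_constant(self, rng):
        s = make_sign_matrix(17, 9, dale=True, rng=rng)
        assert np.all(np.abs(s) == 1)
        for j in range(9):
            assert len(np.unique(s[:, j])) == 1

    def test_nondale_roughly_balanced(self):
        s = make_sign_matrix(100, 100, dale=False, rng=np.random.default_rng(0))
        frac = (s > 0).mean()
        assert 0.45 < frac < 0.55

    def test_deterministic_given_seed(self):
        a = make_sign_matrix(6, 5, dale=True, rng=np.random.default_rng(9))
        b = make_sign_matrix(6, 5, dale=True, rng=np.random.default_rng(9))
        assert_array_equal(a, b)


class TestEffectiveWeights:
    @pytest.mark.parametrize(
        "theta,sign,expected",
        [(0.5, -1.0, -0.5), (-0.3, 1.0, 0.0), (0.0, 1.0, 0.0), (0.0, -1.0, 0.0)],
    )
    def test_pointwise(self, theta, sign, expected):
        p = SignedSparseParam(
            signs=np.array([[sign]]), theta=np.array([[theta]]), budget=1
        )
        assert effective_weights(p)[0, 0] == expected

    def test_lipschitz_and_zero_on_dormant(self, rng):
        signs = make_sign_matrix(8, 8, dale=False, rng=rng)
        t1 = rng.normal(size=(8, 8))
        t2 = t1 + rng.normal(scale=0.1, size=(8, 8))
        p1 = SignedSparseParam(signs=signs, theta=t1, budget=4)
        p2 = SignedSparseParam(signs=signs, theta=t2, budget=4)
        w1, w2 = effective_weights(p1), effective_weights(p2)
        assert np.all(np.abs(w1 - w2) <= np.abs(t1 - t2) + 1e-15)
        assert np.all(w1[t1 <= 0] == 0.0)


class TestL1Penalty:
    def test_examples(self):
        signs = np.ones((1, 3))
        p = SignedSparseParam(signs=signs, theta=np.array([[0.2, 0.3, -1.0]]), budget=2)
        assert_allclose(l1_penalty(p, 1.0), 0.5)
        assert l1_penalty(p, 0.0) == 0.0
        p_all_dormant = SignedSparseParam(
            signs=signs, theta=np.array([[-0.1, -0.2, -3.0]]), budget=1
        )
        assert l1_penalty(p_all_dormant, 2.0) == 0.0

    def test_negative_lambda_raises(self):
        p = SignedSparseParam(signs=np.ones((1, 1)), theta=np.ones((1, 1)), budget=1)
        with pytest.raises(ValueError):
            l1_penalty(p, -1.0)


class TestSparsity:
    @pytest.mark.parametrize("budget,total,expected", [(2, 16, 0.875), (16, 16, 0.0), (8, 16, 0.5)])
    def test_levels(self, budget, total, expected, rng):
        p = SignedSparseParam.init_random(4, total // 4, budget, rng)
        assert_allclose(sparsity(p), expected)


class TestRewireStep:
    def test_gradient_growth_picks_most_negative(self, rng):
        theta = np.array([[-1.0, -1.0, -1.0, 1.0]])
        grads = np.array([[-3.0, -1.0, 2.0, 0.5]])
        p = SignedSparseParam(signs=np.ones((1, 4)), theta=theta, budget=2)
        p, log = rewire_step(p, grads, RewirePolicy(grow_mode="gradient"), rng)
        assert_array_equal(log.grown, [0])
        assert p.theta[0, 0] == RewirePolicy().theta_init

    def test_noop_when_budget_met(self, rng):
        theta = np.array([[0.5, -0.5], [0.3, -0.3]])
        p = SignedSparseParam(signs=np.ones((2, 2)), theta=theta, budget=2)
        before = p.theta.copy()
        p, log = rewire_step(p, np.zeros((2, 2)), RewirePolicy(), rng)
        assert log.n_grown == 0
        assert_array_equal(p.theta, before)

    def test_matches_bruteforce_sort_oracle(self, rng):
        """Gradient growth equals sorting -grad over dormant entries."""
        for _ in range(20):
            theta = rng.normal(size=(20, 20))
            budget = int((theta > 0).sum()) + 30
            p = SignedSparseParam(
                signs=make_sign_matrix(20, 20, dale=True, rng=rng), theta=theta.copy(), budget=budget
            )
            grads = rng.normal(size=(20, 20))
            p, log = rewire_step(p, grads, RewirePolicy(grow_mode="gradient"), rng)
            dormant = np.flatnonzero(theta <= 0)
            neg = dormant[grads.flat[dormant] < 0]
            expected = neg[np.argsort(grads.flat[neg], kind="stable")][:30]
            if len(expected) == 30:  # else random fill kicks in
                assert_array_equal(log.grown, np.sort(expected))

    def test_budget_conserved_over_200_steps(self, rng):
        p = SignedSparseParam.init_random(16, 16, budget=32, rng=rng)
        signs0 = p.signs.copy()
        policy = RewirePolicy(grow_mode="gradient")
        for _ in range(200):
            # simulate optimizer noise pushing some magnitudes negative
            p.theta -= np.abs(rng.normal(scale=0.05, size=p.theta.shape)) * (
                rng.random(p.theta.shape) < 0.2
            )
            p, _ = rewire_step(p, rng.normal(size=p.theta.shape), policy, rng)
            assert p.n_active == 32
        assert_array_equal(p.signs, signs0)

    def test_random_mode_restores_budget(self, rng):
        p = SignedSparseParam(
            signs=np.ones((2, 2)),
            theta=np.array([[-1.0, -1.0], [-1.0, 0.5]]),
            budget=3,
        )
        p, log = rewire_step(p, np.zeros((2, 2)), RewirePolicy(grow_mode="random"), rng)
        assert p.n_active == 3
        assert log.n_grown == 2

    def test_dale_signs_immutable_through_rewiring(self, rng):
        p = SignedSparseParam.init_random(10, 10, budget=20, rng=rng, dale=True)
        col_signs = p.signs[0].copy()
        for _ in range(50):
            p.theta -= 0.1 * (rng.random(p.theta.shape) < 0.3)
            p, _ = rewire_step(p, rng.normal(size=(10, 10)), RewirePolicy(), rng)
        w = effective_weights(p)
        for j in range(10):
            nz = w[:, j][w[:, j] != 0]
            assert np.all(np.sign(nz) == col_signs[j])


class TestPolicyValidation:
    def test_bad_grow_mode(self):
        with pytest.raises(ValueError):
            RewirePolicy(grow_mode="momentum")

    def test_bad_theta_init(self):
        with pytest.raises(ValueError):
            RewirePolicy(theta_init=0.0)
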