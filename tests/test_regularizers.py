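"""Proximal operators against closed-form examples and the numerical oracle,
plus the HSIC estimator against a brute-force Gram computation."""

import numpy as np
import pytest

from oracles import numeric_prox
from progmap.gene_sets import GPMask
from progmap.regularizers import (
    ProxConfig,
    apply_prox,
    column_prox,
    group_lasso_prox,
    hsic,
    hsic_total,
    l1_prox,
    masked_l1_prox,
    median_bandwidth,
    soft_mask_penalty,
)

rng = np.random.default_rng(7)


class TestClosedForms:
    def test_soft_threshold_examples(self):
        np.testing.assert_allclose(l1_prox([2.0, -2.0, 0.3], 0.5), [1.5, -1.5, 0.0])
        v = rng.normal(size=6)
        np.testing.assert_array_equal(l1_prox(v, 0.0), v)

    def test_group_lasso_examples(self):
        np.testing.assert_allclose(group_lasso_prox([3.0, 4.0], 1.0), [2.4, 3.2])
        np.testing.assert_array_equal(group_lasso_prox([0.1, 0.1], 1.0), [0.0, 0.0])

    def test_masked_threshold_examples(self):
        np.testing.assert_allclose(masked_l1_prox([2.0, 2.0], [0, 1], 0.5), [2.0, 1.5])
        v = rng.normal(size=5)
        np.testing.assert_array_equal(masked_l1_prox(v, np.zeros(5), 0.9), v)

    def test_masked_threshold_shape_error(self):
        with pytest.raises(ValueError):
            masked_l1_prox([1.0, 2.0], [0], 0.1)

    def test_column_prox_identity_and_zero_branch(self):
        v = rng.normal(size=4)
        np.testing.assert_array_equal(column_prox(v, np.ones(4), 0.0, 0.0), v)
        assert not column_prox([0.01, -0.01], [1, 1], 1.0, 0.1).any()

    def test_exact_zeros_are_positive_zero(self):
        out = l1_prox([-0.3, 0.3], 1.0)
        assert np.signbit(out).sum() == 0  # canonical +0.0, bitwise reproducible


class TestNumericalOracle:
    """Each closed form equals an independent numerical argmin, 250 instances."""

    @pytest.mark.parametrize(
        "op",
        ["l1", "group_lasso", "masked_l1", "composed"],
    )
    def test_matches_numeric_argmin(self, op):
        gen = np.random.default_rng(123)
        worst = 0.0
        for _ in range(250):
            d = int(gen.integers(1, 50))
            v = gen.normal(0, 2.0, d)
            t1 = 10 ** gen.uniform(-2, 0.7)
            t2 = 10 ** gen.uniform(-2, 0.7)
            m = gen.integers(0, 2, d)
            if op == "l1":
                got, ref = l1_prox(v, t1), numeric_prox(v, 0.0, t1)
            elif op == "group_lasso":
                got, ref = group_lasso_prox(v, t2), numeric_prox(v, t2, 0.0)
            elif op == "masked_l1":
                got, ref = masked_l1_prox(v, m, t1), numeric_prox(v, 0.0, t1, m)
            else:
                got, ref = column_prox(v, m, t2, t1), numeric_prox(v, t2, t1, m)
            worst = max(worst, float(np.abs(got - ref).max()))
        assert worst < 1e-6

    def test_composition_equals_joint_prox(self):
        """Masked soft-threshold then group shrinkage solves the joint problem."""
        gen = np.random.default_rng(5)
        for _ in range(100):
            d = int(gen.integers(2, 30))
            v = gen.normal(0, 2.0, d)
            m = gen.integers(0, 2, d)
            ta, tg = 10 ** gen.uniform(-2, 0.5), 10 ** gen.uniform(-2, 0.5)
            composed = group_lasso_prox(masked_l1_prox(v, m, tg), ta)
            joint = numeric_prox(v, ta, tg, m)
            np.testing.assert_allclose(composed, joint, atol=1e-6)

    def test_firm_nonexpansiveness(self):
        gen = np.random.default_rng(9)
        for _ in range(100):
            d = int(gen.integers(1, 20))
            u, v = gen.normal(0, 3, d), gen.normal(0, 3, d)
            m = gen.integers(0, 2, d)
            pu = column_prox(u, m, 0.8, 0.4)
            pv = column_prox(v, m, 0.8, 0.4)
            assert np.linalg.norm(pu - pv) <= np.linalg.norm(u - v) + 1e-12


class TestApplyProx:
    @pytest.fixture()
    def mask(self):
        B = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]], dtype=np.int8)
        return GPMask(
            program_names=["hardp", "softp", "sparse"],
            gene_names=[f"g{i}" for i in range(5)],
            B=B,
            M=(1 - B).astype(np.int8),
            membership_mode=["hard", "soft", "unconstrained-sparse"],
        )

    def test_zero_strengths_only_enforce_hard_mask(self, mask):
        W = rng.normal(size=(5, 3))
        out = apply_prox(W, mask, ProxConfig(alpha=0, gamma=0, gamma_ext=0, alpha_l1=0, eta=0.1))
        np.testing.assert_array_equal(out[:, 0], W[:, 0] * mask.B[:, 0])
        np.testing.assert_array_equal(out[:, 1:], W[:, 1:])

    def test_per_column_agreement_with_oracle(self, mask):
        W = np.random.default_rng(2).normal(0, 1.5, (5, 3))
        cfg = ProxConfig(alpha=0.6, gamma=0.3, eta=0.05)
        out = apply_prox(W, mask, cfg)
        # hard column: members group-lasso shrunk after zeroing non-members
        ref0 = numeric_prox(W[:, 0] * mask.B[:, 0], cfg.eta * cfg.alpha, 0.0)
        np.testing.assert_allclose(out[:, 0], ref0, atol=1e-6)
        # soft column: joint masked L1 + group lasso
        ref1 = numeric_prox(W[:, 1], cfg.eta * cfg.alpha, cfg.eta * cfg.gamma, mask.M[:, 1])
        np.testing.assert_allclose(out[:, 1], ref1, atol=1e-6)
        # sparse column behaves as soft with all-one mask
        ref2 = numeric_prox(W[:, 2], cfg.eta * cfg.alpha, cfg.eta * cfg.gamma, np.ones(5))
        np.testing.assert_allclose(out[:, 2], ref2, atol=1e-6)

    def test_frozen_columns_untouched_and_unknown_role_rejected(self, mask):
        W = rng.normal(size=(5, 3))
        out = apply_prox(W, mask, ProxConfig(eta=0.1), frozen_columns=[1])
        np.testing.assert_array_equal(out[:, 1], W[:, 1])
        with pytest.raises(ValueError, match="role"):
            apply_prox(W, mask, ProxConfig(eta=0.1), column_roles=["hard", "soft", "bogus"])

    def test_new_column_roles_use_their_own_strengths(self, mask):
        W = np.array([[2.0, 2.0], [-2.0, -2.0], [0.1, 0.1], [1.0, 1.0], [0.0, 0.0]])
        m2 = GPMask(
            program_names=["ext", "newc"],
            gene_names=mask.gene_names,
            B=np.array([[0, 1], [0, 1], [0, 0], [0, 0], [0, 0]], dtype=np.int8),
            M=np.array([[1, 0], [1, 0], [1, 1], [1, 1], [1, 1]], dtype=np.int8),
            membership_mode=["new_unconstrained", "new_constrained_soft"],
        )
        cfg = ProxConfig(alpha=5.0, gamma=5.0, gamma_ext=0.5, alpha_l1=0.5, eta=1.0)
        out = apply_prox(W, m2, cfg)
        np.testing.assert_allclose(out[:, 0], l1_prox(W[:, 0], 0.5))  # no group lasso
        np.testing.assert_allclose(out[:, 1], masked_l1_prox(W[:, 1], m2.M[:, 1], 0.5))


class TestSoftMaskPenalty:
    def test_zero_cases_and_direct_sum(self):
        W = rng.normal(size=(4, 2))
        M = rng.integers(0, 2, (4, 2))
        assert soft_mask_penalty(np.zeros_like(W), M, 0.7) == 0.0
        assert soft_mask_penalty(W, np.zeros_like(M), 0.7) == 0.0
        expected = 0.7 * np.abs(W * M).sum()
        assert soft_mask_penalty(W, M, 0.7) == pytest.approx(expected)


class TestHSIC:
    def test_matches_double_loop_gram(self):
        x = rng.normal(size=25)
        Y = rng.normal(size=(25, 3))
        # same centering algebra: H K H L -> use direct definition
        n = 25
        H = np.eye(n) - np.ones((n, n)) / n

        def gram(A):
            bw = median_bandwidth(A)
            K = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    K[i, j] = np.exp(-np.sum((A[i] - A[j]) ** 2) / (2 * bw * bw))
            return K

        ref = np.trace((H @ gram(x.reshape(-1, 1)) @ H) @ (H @ gram(Y) @ H)) / (n - 1) ** 2
        assert abs(hsic(x, Y) - ref) < 1e-10

    def test_constant_input_gives_zero(self):
        assert hsic(np.full(12, 3.0), rng.normal(size=(12, 2))) == pytest.approx(0.0, abs=1e-12)

    def test_dependent_exceeds_permuted_null(self):
        gen = np.random.default_rng(11)
        wins = 0
        x = gen.normal(size=200)
        dep = hsic(x, x.reshape(-1, 1))
        for _ in range(100):
            wins += dep > hsic(x, gen.permutation(x).reshape(-1, 1))
        assert wins >= 99

    def test_shift_and_joint_permutation_invariance(self):
        x = rng.normal(size=40)
        Y = rng.normal(size=(40, 2))
        base = hsic(x, Y)
        assert hsic(x + 100.0, Y) == pytest.approx(base, rel=1e-9)
        perm = rng.permutation(40)
        assert hsic(x[perm], Y[perm]) == pytest.approx(base, rel=1e-9)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            hsic(np.ones(3), np.ones((3, 1)))

    def test_total_sums_each_new_node_against_the_rest(self):
        Z = rng.normal(size=(30, 4))
        expected = hsic(Z[:, 2], Z[:, [0, 1, 3]]) + hsic(Z[:, 3], Z[:, [0, 1, 2]])
        assert hsic_total(Z, [2, 3]) == pytest.approx(expected, rel=1e-12)
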