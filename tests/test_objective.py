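import numpy as np
import pytest

from mmdma.objective import (
    distortion_term,
    embed,
    mmd_squared,
    multi_objective,
    objective,
    objective_with_grad,
    penalty_term,
)
from mmdma.optimizer import Hyperparameters


def brute_force_mmd2(U1, U2, sigma):
    """Independent triple-double-loop evaluation of the V-statistic."""

    def k(u, v):
        return np.exp(-np.sum((u - v) ** 2) / (2.0 * sigma**2))

    n1, n2 = len(U1), len(U2)
    s11 = sum(k(U1[i], U1[j]) for i in range(n1) for j in range(n1))
    s12 = sum(k(U1[i], U2[j]) for i in range(n1) for j in range(n2))
    s22 = sum(k(U2[i], U2[j]) for i in range(n2) for j in range(n2))
    return s11 / n1**2 - 2.0 * s12 / (n1 * n2) + s22 / n2**2


class TestMMDSquared:
    def test_matches_brute_force_loops(self, rng):
        U1 = rng.standard_normal((7, 3))
        U2 = rng.standard_normal((5, 3))
        assert mmd_squared(U1, U2, 0.8) == pytest.approx(
            brute_force_mmd2(U1, U2, 0.8), abs=1e-12
        )

    def test_identical_point_sets_give_zero(self, rng):
        U = rng.standard_normal((10, 4))
        assert abs(mmd_squared(U, U, 1.3)) < 1e-12

    def test_coincident_singletons_give_zero(self):
        assert mmd_squared([[0.0, 0.0]], [[0.0, 0.0]], 2.0) == pytest.approx(0.0)

    def test_symmetric_in_arguments(self, rng):
        U1 = rng.standard_normal((6, 2))
        U2 = rng.standard_normal((9, 2))
        assert mmd_squared(U1, U2, 0.7) == pytest.approx(
            mmd_squared(U2, U1, 0.7), abs=1e-14
        )

    def test_invariant_under_joint_rigid_translation(self, rng):
        U1 = rng.standard_normal((6, 3))
        U2 = rng.standard_normal((8, 3))
        shift = rng.standard_normal(3)
        assert mmd_squared(U1 + shift, U2 + shift, 0.9) == pytest.approx(
            mmd_squared(U1, U2, 0.9), abs=1e-12
        )

    def test_nonnegative_and_vanishing_for_large_bandwidth(self, rng):
        # once sigma exceeds the separation of the clouds the RBF kernel
        # flattens toward a constant, so MMD^2 decays monotonically to 0
        U1 = rng.standard_normal((8, 2))
        U2 = rng.standard_normal((8, 2)) + 2.0
        values = [mmd_squared(U1, U2, s) for s in (8.0, 32.0, 128.0, 512.0)]
        assert all(v >= -1e-10 for v in values)
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] < 1e-4

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            mmd_squared(rng.standard_normal((4, 2)), rng.standard_normal((4, 3)), 1.0)

    def test_linear_estimator_agrees_in_expectation(self, rng):
        # The streaming estimator is unbiased for the population MMD^2, i.e.
        # for the U-statistic (the V-statistic carries an O(1/n) diagonal
        # bias), so its average over row shuffles must approach the
        # U-statistic computed on the same sample.
        n = 400
        U1 = rng.standard_normal((n, 2))
        U2 = rng.standard_normal((n, 2)) + 0.3

        def k(u, v):
            d = ((u[:, None, :] - v[None, :, :]) ** 2).sum(-1)
            return np.exp(-d / 2.0)

        G11, G12, G22 = k(U1, U1), k(U1, U2), k(U2, U2)
        u_stat = (
            (G11.sum() - np.trace(G11)) / (n * (n - 1))
            - 2.0 * G12.mean()
            + (G22.sum() - np.trace(G22)) / (n * (n - 1))
        )
        reps = [
            mmd_squared(
                U1[rng.permutation(n)], U2[rng.permutation(n)], 1.0,
                estimator="linear",
            )
            for _ in range(60)
        ]
        assert np.mean(reps) == pytest.approx(u_stat, abs=3e-3)


class TestPenaltyTerm:
    def test_zero_when_alpha_t_K_alpha_is_identity(self):
        n, p = 6, 3
        assert penalty_term(np.eye(n)[:, :p], np.eye(n)) == pytest.approx(0.0)

    def test_zero_alpha_gives_p(self):
        assert penalty_term(np.zeros((5, 2)), np.eye(5)) == pytest.approx(2.0)

    def test_matches_elementwise_loop(self, rng, psd_kernel):
        K = psd_kernel(5)
        alpha = rng.standard_normal((5, 2))
        M = alpha.T @ K @ alpha - np.eye(2)
        brute = sum(M[i, j] ** 2 for i in range(2) for j in range(2))
        assert penalty_term(alpha, K) == pytest.approx(brute, abs=1e-12)

    def test_shape_mismatch_raises(self, rng, psd_kernel):
        with pytest.raises(ValueError, match="mismatch"):
            penalty_term(rng.standard_normal((4, 2)), psd_kernel(5))


class TestDistortionTerm:
    def test_zero_for_identity_kernel_full_rank_alpha(self):
        assert distortion_term(np.eye(4), np.eye(4)) == pytest.approx(0.0)

    def test_zero_alpha_gives_squared_frobenius_of_K(self, psd_kernel):
        K = psd_kernel(6)
        assert distortion_term(np.zeros((6, 2)), K) == pytest.approx(
            float((K**2).sum())
        )

    def test_matches_elementwise_loop(self, rng, psd_kernel):
        K = psd_kernel(5)
        alpha = rng.standard_normal((5, 2))
        R = K - K @ alpha @ alpha.T @ K.T
        brute = sum(R[i, j] ** 2 for i in range(5) for j in range(5))
        assert distortion_term(alpha, K) == pytest.approx(brute, rel=1e-10)


class TestEmbed:
    def test_identity_kernel_returns_alpha(self, rng):
        alpha = rng.standard_normal((4, 2))
        np.testing.assert_array_equal(embed(np.eye(4), alpha), alpha)

    def test_matches_loop_matrix_product(self, rng, psd_kernel):
        K = psd_kernel(5)
        alpha = rng.standard_normal((5, 3))
        brute = np.array(
            [[sum(K[i, l] * alpha[l, j] for l in range(5)) for j in range(3)]
             for i in range(5)]
        )
        np.testing.assert_allclose(embed(K, alpha), brute, atol=1e-12)


class TestObjective:
    def test_zero_weights_reduce_to_mmd_alone(self, rng, psd_kernel):
        K1, K2 = psd_kernel(6), psd_kernel(8)
        a1 = rng.standard_normal((6, 2))
        a2 = rng.standard_normal((8, 2))
        hp = Hyperparameters(p=2, lambda1=0.0, lambda2=0.0, sigma=0.9)
        val = objective(a1, a2, K1, K2, hp)
        assert val.total == pytest.approx(
            mmd_squared(K1 @ a1, K2 @ a2, 0.9), abs=1e-14
        )

    def test_zero_alphas_closed_form(self, psd_kernel):
        K = psd_kernel(5)
        p, lam1, lam2 = 3, 0.4, 0.7
        hp = Hyperparameters(p=p, lambda1=lam1, lambda2=lam2, sigma=1.0)
        val = objective(np.zeros((5, p)), np.zeros((5, p)), K, K, hp)
        assert val.mmd2 == pytest.approx(0.0, abs=1e-12)
        assert val.total == pytest.approx(
            lam1 * 2 * p + lam2 * 2 * float((K**2).sum()), rel=1e-12
        )

    def test_components_recompute_independently(self, rng, psd_kernel):
        K1, K2 = psd_kernel(7), psd_kernel(5)
        a1 = rng.standard_normal((7, 3)) * 0.3
        a2 = rng.standard_normal((5, 3)) * 0.3
        hp = Hyperparameters(p=3, lambda1=0.2, lambda2=0.05, sigma=0.6)
        val = objective(a1, a2, K1, K2, hp)
        assert val.mmd2 == pytest.approx(
            brute_force_mmd2(K1 @ a1, K2 @ a2, 0.6), abs=1e-12
        )
        assert val.pen1 == pytest.approx(penalty_term(a1, K1), abs=1e-12)
        assert val.dis2 == pytest.approx(distortion_term(a2, K2), abs=1e-12)
        recomputed = (
            val.mmd2 + 0.2 * (val.pen1 + val.pen2) + 0.05 * (val.dis1 + val.dis2)
        )
        assert val.total == pytest.approx(recomputed, rel=1e-10)

    def test_three_domain_objective_sums_pairwise_mmd(self, rng, psd_kernel):
        Ks = [psd_kernel(n) for n in (5, 6, 7)]
        alphas = [rng.standard_normal((K.shape[0], 2)) * 0.4 for K in Ks]
        val = multi_objective(alphas, Ks, lambda1=0.0, lambda2=0.0, sigma=0.8)
        Us = [K @ a for K, a in zip(Ks, alphas)]
        expected = (
            mmd_squared(Us[0], Us[1], 0.8)
            + mmd_squared(Us[0], Us[2], 0.8)
            + mmd_squared(Us[1], Us[2], 0.8)
        )
        assert val.total == pytest.approx(expected, abs=1e-12)


class TestGradients:
    @pytest.mark.parametrize("estimator", ["quadratic", "linear"])
    def test_analytic_gradients_match_central_differences(self, estimator):
        rng = np.random.default_rng(7)
        n, p = 10, 2
        Ks = []
        for _ in range(2):
            A = rng.standard_normal((n, n))
            Ks.append((A @ A.T) / n)
        alphas = [rng.standard_normal((n, p)) * 0.2 for _ in range(2)]
        kw = dict(lambda1=0.3, lambda2=0.15, sigma=0.7, estimator=estimator)
        _, grads = objective_with_grad(alphas, Ks, **kw)
        h = 1e-5
        for d in range(2):
            num = np.zeros((n, p))
            for i in range(n):
                for j in range(p):
                    for sign, store in ((1, "plus"), (-1, "minus")):
                        perturbed = [a.copy() for a in alphas]
                        perturbed[d][i, j] += sign * h
                        v, _ = objective_with_grad(
                            perturbed, Ks, need_grad=False, **kw
                        )
                        if store == "plus":
                            plus = v.total
                        else:
                            minus = v.total
                    num[i, j] = (plus - minus) / (2 * h)
            denom = max(np.abs(num).max(), 1e-12)
            assert np.abs(num - grads[d]).max() / denom < 1e-4
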