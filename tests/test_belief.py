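"""Belief models: Jacobian assembly, Householder covariance, closed-form KL."""

import numpy as np
import pytest

from hhvg.belief import (
    ForwardModel,
    GaussianBelief,
    MetaModel,
    devaluation_objective,
    gaussian_kl,
    gaussian_kl_diag_q,
    householder_orthogonal,
)
from hhvg.nets import Adam
from tests.conftest import finite_difference_check


class TestForwardModel:
    def test_jacobian_shapes(self, small_fm, rng):
        s = rng.normal(size=(3, 4))
        A, B, C, o = small_fm.jacobians(s)
        assert A.shape == (3, 4, 4)
        assert B.shape == (3, 2, 4, 4)
        assert C.shape == (3, 4, 2)
        assert o.shape == (3, 4)

    def test_deterministic_outputs(self, small_fm, rng):
        s = rng.normal(size=(2, 4))
        a = rng.normal(size=(2, 2))
        assert np.array_equal(small_fm.mean(s, a), small_fm.mean(s, a))

    def test_identity_dynamics_mean(self, small_fm):
        """With A=I, B=C=o=0 forced, the predicted mean is the state itself."""
        for head, val in ((small_fm.head_A, np.eye(4).ravel()),
                          (small_fm.head_B, np.zeros(32)),
                          (small_fm.head_C, np.zeros(8)),
                          (small_fm.head_o, np.zeros(4))):
            head.W[...] = 0.0
            head.b[...] = val
        s = np.array([[0.3, -1.2, 0.5, 2.0]])
        a = np.array([[0.7, -0.4]])
        assert np.allclose(small_fm.mean(s, a), s)

    def test_zero_action_covariance_is_ASAt(self, small_fm, rng):
        """At a = 0, J = A and the covariance reduces to sigma^2 A A^T."""
        s = rng.normal(size=(1, 4))
        A, _, _, _ = small_fm.jacobians(s)
        _, cov = small_fm.predict_batch(s, np.zeros((1, 2)))
        expected = small_fm.sigma_s**2 * A[0] @ A[0].T
        assert np.allclose(cov[0], expected)

    def test_finite_difference_jacobian_with_constant_heads(self, small_fm):
        """With heads frozen to constants, df/ds equals A + sum_i a_i B_i."""
        rng = np.random.default_rng(3)
        for head in (small_fm.head_A, small_fm.head_B, small_fm.head_C,
                     small_fm.head_o):
            head.W[...] = 0.0
            head.b[...] = rng.normal(size=head.b.shape) * 0.5
        s = rng.normal(size=4)
        a = rng.normal(size=2)
        A, B, _, _ = small_fm.jacobians(s[None])
        J = A[0] + a[0] * B[0, 0] + a[1] * B[0, 1]
        eps = 1e-6
        J_fd = np.empty((4, 4))
        for j in range(4):
            sp, sm = s.copy(), s.copy()
            sp[j] += eps
            sm[j] -= eps
            J_fd[:, j] = (small_fm.mean(sp[None], a[None])[0]
                          - small_fm.mean(sm[None], a[None])[0]) / (2 * eps)
        assert np.allclose(J, J_fd, atol=1e-6)

    def test_mean_bilinear_in_state_for_frozen_outputs(self, small_fm, rng):
        """f is affine in s once A, B, C, o are held fixed."""
        s1, s2 = rng.normal(size=(2, 4))
        a = rng.normal(size=2)
        A, B, C, o = small_fm.jacobians(s1[None])
        f = lambda s: ForwardModel.assemble_mean(A, B, C, o, s[None], a[None])[0]
        lhs = f(s1 + s2) - f(np.zeros(4))
        rhs = (f(s1) - f(np.zeros(4))) + (f(s2) - f(np.zeros(4)))
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_sample_covariance_matches_JSJt(self, small_fm, rng):
        belief = small_fm.predict(rng.normal(size=4), rng.normal(size=2))
        draws = belief.sample(np.random.default_rng(0), 100_000)
        emp = np.cov(draws.T)
        scale = np.sqrt(np.outer(np.diag(belief.cov), np.diag(belief.cov)))
        assert np.all(np.abs(emp - belief.cov) < 0.05 * scale + 1e-7)

    def test_mse_gradients_match_finite_differences(self, small_fm, rng):
        s = rng.normal(size=(5, 4))
        a = rng.normal(size=(5, 2))
        sn = rng.normal(size=(5, 4))
        err = finite_difference_check(
            small_fm,
            lambda: small_fm.mse_backward(s, a, sn),
            lambda: float(np.mean(small_fm.mse_losses(s, a, sn))),
        )
        assert err < 1e-5

    def test_scalar_offset_option(self, rng):
        fm = ForwardModel(rng, width=8, o_scalar=True)
        _, _, _, o = fm.jacobians(rng.normal(size=(3, 4)))
        assert o.shape == (3, 4)
        assert np.allclose(o, o[:, :1])  # broadcast of the single element


class TestHouseholder:
    def test_axis_reflection(self):
        H = householder_orthogonal(np.array([1.0, 0, 0, 0]))
        assert np.allclose(H, np.diag([-1.0, 1, 1, 1]))

    def test_orthogonal_symmetric_det_minus_one(self, rng):
        for _ in range(20):
            H = householder_orthogonal(rng.normal(size=4))
            assert np.allclose(H @ H.T, np.eye(4), atol=1e-10)
            assert np.allclose(H, H.T, atol=1e-12)
            assert np.isclose(np.linalg.det(H), -1.0)

    def test_isometry(self, rng):
        H = householder_orthogonal(rng.normal(size=4))
        for _ in range(10):
            x = rng.normal(size=4)
            assert abs(np.linalg.norm(H @ x) - np.linalg.norm(x)) < 1e-10

    def test_scale_invariance(self, rng):
        u = rng.normal(size=4)
        assert np.allclose(householder_orthogonal(u), householder_orthogonal(2 * u))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            householder_orthogonal(np.zeros(4))


class TestMetaModel:
    def test_unit_spectrum_gives_identity_covariance(self, small_mm, rng):
        # force d = softplus(b) = 1 regardless of u
        small_mm.head_d.W[...] = 0.0
        small_mm.head_d.b[...] = np.log(np.e - 1.0)
        belief = small_mm.predict(rng.normal(size=4))
        assert np.allclose(belief.cov, np.eye(4), atol=1e-9)

    def test_forced_spectrum_and_axis(self, small_mm, rng):
        """d = (4,1,1,1) with u = e1 gives covariance diag(4,1,1,1)."""
        small_mm.head_d.W[...] = 0.0
        small_mm.head_d.b[...] = np.log(np.expm1(np.array([4.0, 1, 1, 1])))
        small_mm.head_u.W[...] = 0.0
        small_mm.head_u.b[...] = np.array([1.0, 0, 0, 0])
        belief = small_mm.predict(rng.normal(size=4))
        assert np.allclose(belief.cov, np.diag([4.0, 1, 1, 1]), atol=1e-8)

    def test_covariance_eigenvalues_equal_spectrum(self, small_mm, rng):
        s = rng.normal(size=(6, 4))
        mu, d, H = small_mm.outputs(s)
        cov = np.einsum("nij,nj,nkj->nik", H, d, H)
        for i in range(6):
            assert np.allclose(cov[i], cov[i].T, atol=1e-10)
            eig = np.sort(np.linalg.eigvalsh(cov[i]))
            assert np.allclose(eig, np.sort(d[i]), atol=1e-6)
            assert eig.min() > 0

    def test_kl_gradients_match_finite_differences(self, small_mm, small_fm, rng):
        s = rng.normal(size=(4, 4))
        a = rng.normal(size=(4, 2))
        mu_p, cov_p = small_fm.predict_batch(s, a)
        err = finite_difference_check(
            small_mm,
            lambda: small_mm.kl_backward(mu_p, cov_p, s),
            lambda: float(np.mean(small_mm.kl_values(mu_p, cov_p, s))),
            eps=1e-5,
        )
        assert err < 1e-4


class TestGaussianKL:
    def test_identical_beliefs_zero(self, rng):
        cov = np.eye(4) * 0.5
        b = GaussianBelief(rng.normal(size=4), cov)
        assert abs(gaussian_kl(b, b)) < 1e-12

    def test_shifted_isotropic_closed_form(self, rng):
        """KL(N(0,I) || N(mu,I)) = ||mu||^2 / 2."""
        mu = rng.normal(size=4)
        p = GaussianBelief(np.zeros(4), np.eye(4))
        q = GaussianBelief(mu, np.eye(4))
        assert np.isclose(gaussian_kl(p, q), 0.5 * mu @ mu)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(200):
            Ap = rng.normal(size=(4, 4))
            Aq = rng.normal(size=(4, 4))
            p = GaussianBelief(rng.normal(size=4), Ap @ Ap.T + 0.1 * np.eye(4))
            q = GaussianBelief(rng.normal(size=4), Aq @ Aq.T + 0.1 * np.eye(4))
            assert gaussian_kl(p, q) >= 0.0

    def test_singular_q_raises_with_jitter_hint(self):
        p = GaussianBelief(np.zeros(4), np.eye(4))
        q = GaussianBelief(np.zeros(4), np.zeros((4, 4)))
        with pytest.raises(np.linalg.LinAlgError, match="jitter"):
            gaussian_kl(p, q)

    def test_matches_monte_carlo(self, rng):
        """Closed form vs E_p[log p - log q] over 10^6 samples, 3 SE."""
        from scipy.stats import multivariate_normal

        for trial in range(3):
            Ap = rng.normal(size=(4, 4))
            Aq = rng.normal(size=(4, 4))
            p = GaussianBelief(rng.normal(size=4), Ap @ Ap.T + 0.2 * np.eye(4))
            q = GaussianBelief(rng.normal(size=4), Aq @ Aq.T + 0.2 * np.eye(4))
            draws = p.sample(np.random.default_rng(trial), 1_000_000)
            lr = (multivariate_normal.logpdf(draws, p.mean, p.cov)
                  - multivariate_normal.logpdf(draws, q.mean, q.cov))
            mc = lr.mean()
            se = lr.std(ddof=1) / np.sqrt(len(lr))
            assert abs(gaussian_kl(p, q) - mc) < 3 * se

    def test_diag_form_agrees_with_generic(self, small_mm, small_fm, rng):
        s = rng.normal(size=(5, 4))
        a = rng.normal(size=(5, 2))
        mu_p, cov_p = small_fm.predict_batch(s, a)
        mu_q, d, H = small_mm.outputs(s)
        fast = gaussian_kl_diag_q(mu_p, cov_p, mu_q, d, H)
        for i in range(5):
            cov_q = H[i] @ np.diag(d[i]) @ H[i].T
            ref = gaussian_kl(GaussianBelief(mu_p[i], cov_p[i]),
                              GaussianBelief(mu_q[i], cov_q))
            assert np.isclose(fast[i], ref, rtol=1e-3)


class TestDevaluationObjective:
    def test_zero_when_meta_matches_forward_belief(self, small_fm, rng):
        """A meta-model forced onto the target belief gives (near-)zero KL."""
        s = rng.normal(size=4)
        mean = small_fm.predict(s, rng.normal(size=2)).mean
        target = GaussianBelief(mean, np.eye(4) * 0.7)
        mm = MetaModel(rng, width=8)
        mm.head_mu.W[...] = 0.0
        mm.head_mu.b[...] = target.mean
        mm.head_d.W[...] = 0.0
        mm.head_d.b[...] = np.log(np.expm1(0.7))  # softplus^-1(0.7)
        assert gaussian_kl(target, mm.predict(s)) < 1e-8

    def test_descent_step_decreases_objective(self, small_fm, small_mm, rng):
        s = rng.normal(size=(8, 4))
        a = rng.normal(size=(8, 2))
        mu_p, cov_p = small_fm.predict_batch(s, a)
        before = float(np.mean(small_mm.kl_values(mu_p, cov_p, s)))
        opt = Adam(small_mm.parameters(), lr=1e-3)
        small_mm.zero_grad()
        small_mm.kl_backward(mu_p, cov_p, s)
        opt.step()
        after = float(np.mean(small_mm.kl_values(mu_p, cov_p, s)))
        assert after < before

    def test_invariant_to_householder_sign(self, small_fm, small_mm, rng):
        s = rng.normal(size=4)
        a = rng.normal(size=2)
        val = devaluation_objective(a, s, small_fm, small_mm)
        small_mm.head_u.W[...] *= -1.0
        small_mm.head_u.b[...] *= -1.0
        assert np.isclose(val, devaluation_objective(a, s, small_fm, small_mm))
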