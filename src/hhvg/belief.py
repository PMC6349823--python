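"""Gaussian belief models: the bilinear forward model and the meta-model.

Two probabilistic models sit at the heart of the agent:

* the **forward model** P(S'|a, s; theta) — a locally-linear transition
  model.  A residual MLP trunk reads the state and emits, through four linear
  heads, the Jacobian blocks A (4x4), B (2x4x4), C (4x2) and an offset o, from
  which the predictive mean is assembled bilinearly,

      f(a, s) = A s + (sum_i a_i B_i) s + C a + o,

  with covariance J Sigma J^T for J = A + sum_i a_i B_i and a fixed isotropic
  base covariance Sigma = sigma_s^2 I (the environment itself is
  deterministic; Sigma only shapes the KL geometry);

* the **meta-model** Q(S'|s; psi) — a Gaussian summary of where the agent
  tends to end up from s, marginalising over its own actions.  Three
  identically structured towers emit the mean mu', a positive spectrum d
  (Softplus) and a Householder vector u; the covariance is the
  eigendecomposition Sigma' = H diag(d) H^T with H = I - 2 u u^T / ||u||^2,
  guaranteeing symmetric positive-definiteness for free.

Fitting the meta-model to the forward model's predictions under the running
policy is *devaluation*: the closed-form Gaussian KL between the two beliefs
is the devaluation objective, and its decrease across one meta-model update
is the intrinsic reward (see :mod:`hhvg.rewards`).

Gradients here are analytic (no autodiff is used anywhere in the package) and
each backward pass is finite-difference-checked in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nets import Linear, ResidualMLP, sigmoid, softplus

__all__ = [
    "GaussianBelief",
    "ForwardModel",
    "MetaModel",
    "householder_orthogonal",
    "gaussian_kl",
    "gaussian_kl_diag_q",
    "devaluation_objective",
]

STATE_DIM = 4
ACTION_DIM = 2
KL_JITTER = 1e-6


@dataclass
class GaussianBelief:
    """A Gaussian over the next state: mean (4,) and covariance (4, 4)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (STATE_DIM,) or self.cov.shape != (STATE_DIM, STATE_DIM):
            raise ValueError("GaussianBelief expects a 4-dim mean and 4x4 covariance")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.multivariate_normal(self.mean, self.cov, size=n, method="svd")


def householder_orthogonal(u: np.ndarray) -> np.ndarray:
    """Householder reflection H = I - 2 u u^T / ||u||^2.

    H is symmetric, orthogonal, and has determinant -1.  Invariant to the
    scale of ``u``; a zero vector is rejected.
    """
    u = np.asarray(u, dtype=float)
    n2 = float(u @ u)
    if n2 <= 0.0:
        raise ValueError("Householder vector must be nonzero")
    return np.eye(len(u)) - 2.0 * np.outer(u, u) / n2


def _householder_batch(u: np.ndarray) -> np.ndarray:
    """Batched reflections for u of shape (N, k)."""
    n2 = np.einsum("ni,ni->n", u, u)
    H = np.eye(u.shape[1])[None] - 2.0 * np.einsum("ni,nj->nij", u, u) / n2[:, None, None]
    return H


def gaussian_kl(p: GaussianBelief, q: GaussianBelief) -> float:
    """Closed-form KL(p || q) between two multivariate normals (nats)."""
    k = len(p.mean)
    try:
        Lq = np.linalg.cholesky(q.cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "q covariance is singular; add diagonal jitter (e.g. 1e-6 * I)"
        ) from err
    delta = q.mean - p.mean
    sol_cov = np.linalg.solve(q.cov, p.cov)
    trace_term = np.trace(sol_cov)
    alpha = np.linalg.solve(Lq, delta)
    maha = float(alpha @ alpha)
    sign_p, logdet_p = np.linalg.slogdet(p.cov)
    if sign_p <= 0:
        raise np.linalg.LinAlgError("p covariance must be positive definite")
    logdet_q = 2.0 * np.sum(np.log(np.diag(Lq)))
    return 0.5 * (trace_term + maha - k + logdet_q - logdet_p)


def gaussian_kl_diag_q(mu_p, cov_p, mu_q, d, H) -> np.ndarray:
    """Vectorised KL(N(mu_p, cov_p) || N(mu_q, H diag(d) H^T)) in nats.

    Batched over the leading axes of every argument; exploits the
    eigendecomposed form of the q covariance (inverse and log-determinant are
    O(k) given H and d).  A small jitter stabilises the inversion against
    Softplus underflow.
    """
    d = np.asarray(d, dtype=float) + KL_JITTER
    delta = np.asarray(mu_q) - np.asarray(mu_p)
    # rotate into the eigenbasis of q; H is symmetric so H^T = H
    MH = np.matmul(cov_p, H)
    diag = np.sum(H * MH, axis=-2)  # diag(H^T cov_p H)
    trace_term = np.sum(diag / d, axis=-1)
    w = np.matmul(H, delta[..., None])[..., 0]
    maha = np.sum(w * w / d, axis=-1)
    sign, logdet_p = np.linalg.slogdet(cov_p)
    logdet_q = np.sum(np.log(d), axis=-1)
    k = delta.shape[-1]
    return 0.5 * (trace_term + maha - k + logdet_q - logdet_p)


class ForwardModel:
    """Locally-linear Gaussian transition model P(S'|a, s; theta).

    ``o_scalar=True`` reproduces the literal single-element offset head
    (broadcast over the four state coordinates); the default is a 4-dim
    offset, the only reading under which f lives in state space without
    broadcasting.
    """

    def __init__(self, rng: np.random.Generator, width: int = 512, n_layers: int = 4,
                 sigma_s: float = 0.01, o_scalar: bool = False):
        self.width = width
        self.sigma_s = float(sigma_s)
        self.o_scalar = o_scalar
        self.trunk = ResidualMLP(rng, STATE_DIM, width, n_layers, name="fm.trunk")
        self.head_A = Linear(rng, width, 16, name="fm.A")
        self.head_B = Linear(rng, width, 32, name="fm.B")
        self.head_C = Linear(rng, width, 8, name="fm.C")
        self.head_o = Linear(rng, width, 1 if o_scalar else 4, name="fm.o")
        self.base_cov = self.sigma_s**2 * np.eye(STATE_DIM)

    # -- parameter plumbing ---------------------------------------------
    def parameters(self):
        yield from self.trunk.parameters()
        for h in (self.head_A, self.head_B, self.head_C, self.head_o):
            yield from h.parameters()

    def zero_grad(self):
        self.trunk.zero_grad()
        for h in (self.head_A, self.head_B, self.head_C, self.head_o):
            h.zero_grad()

    def state_dict(self):
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, sd):
        for name, p, _ in self.parameters():
            np.copyto(p, sd[name])

    def copy_from(self, other: "ForwardModel"):
        for (_, p, _), (_, q, _) in zip(self.parameters(), other.parameters()):
            np.copyto(p, q)

    # -- forward passes ---------------------------------------------------
    def jacobians(self, s: np.ndarray, cache: list | None = None):
        """Jacobian blocks (A, B, C, o) at states ``s`` of shape (N, 4).

        Shapes: A (N,4,4), B (N,2,4,4), C (N,4,2), o (N,4).
        """
        s = np.atleast_2d(np.asarray(s, dtype=float))
        h = self.trunk.forward(s, cache)
        A = self.head_A.forward(h).reshape(-1, 4, 4)
        B = self.head_B.forward(h).reshape(-1, 2, 4, 4)
        C = self.head_C.forward(h).reshape(-1, 4, 2)
        o = self.head_o.forward(h)
        if self.o_scalar:
            o = np.broadcast_to(o, (o.shape[0], 4))
        if cache is not None:
            cache.append(h)
        return A, B, C, o

    @staticmethod
    def assemble_mean(A, B, C, o, s, a):
        """f(a,s) = A s + (sum_i a_i B_i) s + C a + o (batched)."""
        Bs = np.einsum("nkij,nj->nki", B, s)
        return (
            np.einsum("nij,nj->ni", A, s)
            + np.einsum("nk,nki->ni", a, Bs)
            + np.einsum("nik,nk->ni", C, a)
            + o
        )

    def mean(self, s: np.ndarray, a: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(np.asarray(s, dtype=float))
        a = np.atleast_2d(np.asarray(a, dtype=float))
        A, B, C, o = self.jacobians(s)
        return self.assemble_mean(A, B, C, o, s, a)

    def predict(self, s, a) -> GaussianBelief:
        """Single-input Gaussian belief N(f(a,s), J Sigma J^T)."""
        s1 = np.atleast_2d(np.asarray(s, dtype=float))
        a1 = np.atleast_2d(np.asarray(a, dtype=float))
        mu, cov = self.predict_batch(s1, a1)
        return GaussianBelief(mu[0], cov[0])

    def predict_batch(self, s: np.ndarray, a: np.ndarray):
        """Batched means (N,4) and covariances (N,4,4)."""
        A, B, C, o = self.jacobians(s)
        mu = self.assemble_mean(A, B, C, o, s, a)
        J = A + np.einsum("nk,nkij->nij", a, B)
        cov = self.sigma_s**2 * np.einsum("nij,nkj->nik", J, J)
        return mu, cov

    def predict_all_actions(self, s: np.ndarray, action_grid: np.ndarray,
                            with_cov: bool = True):
        """Means (N, M, 4) (and covariances (N, M, 4, 4)) for every action.

        One trunk pass per state serves the whole action grid, which is what
        makes exact enumeration of the policy objective affordable.
        """
        s = np.atleast_2d(np.asarray(s, dtype=float))
        A, B, C, o = self.jacobians(s)
        base = np.einsum("nij,nj->ni", A, s) + o  # (N, 4)
        Bs = np.einsum("nkij,nj->nki", B, s)  # (N, 2, 4)
        act_term = np.einsum("mk,nki->nmi", action_grid, Bs + np.swapaxes(C, 1, 2))
        mu = base[:, None, :] + act_term
        if not with_cov:
            return mu, None
        J = A[:, None] + np.einsum("mk,nkij->nmij", action_grid, B)
        cov = self.sigma_s**2 * np.einsum("nmij,nmkj->nmik", J, J)
        return mu, cov

    # -- learning ---------------------------------------------------------
    def mse_losses(self, s, a, s_next) -> np.ndarray:
        """Per-sample squared error ||s' - f(a,s)||^2."""
        err = self.mean(s, a) - np.atleast_2d(s_next)
        return np.sum(err * err, axis=1)

    def mse_backward(self, s, a, s_next) -> float:
        """Accumulate d(mean ||s' - f||^2)/dtheta; returns the batch loss."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        a = np.atleast_2d(np.asarray(a, dtype=float))
        s_next = np.atleast_2d(np.asarray(s_next, dtype=float))
        n = s.shape[0]
        cache: list = []
        A, B, C, o = self.jacobians(s, cache)
        f = self.assemble_mean(A, B, C, o, s, a)
        err = f - s_next
        loss = float(np.mean(np.sum(err * err, axis=1)))
        gf = 2.0 * err / n  # (N, 4)
        h = cache.pop()
        gA = np.einsum("ni,nj->nij", gf, s).reshape(n, 16)
        gB = np.einsum("nk,ni,nj->nkij", a, gf, s).reshape(n, 32)
        gC = np.einsum("ni,nk->nik", gf, a).reshape(n, 8)
        go = gf.sum(axis=1, keepdims=True) if self.o_scalar else gf
        gh = (
            self.head_A.backward(h, gA)
            + self.head_B.backward(h, gB)
            + self.head_C.backward(h, gC)
            + self.head_o.backward(h, go)
        )
        self.trunk.backward(cache, gh)
        return loss


class MetaModel:
    """Gaussian marginal-outcome model Q(S'|s; psi) with Householder covariance."""

    def __init__(self, rng: np.random.Generator, width: int = 512, n_layers: int = 3):
        self.width = width
        # three disjoint, identically structured towers for mu', d, u
        self.trunk_mu = ResidualMLP(rng, STATE_DIM, width, n_layers, name="mm.mu.trunk")
        self.head_mu = Linear(rng, width, 4, name="mm.mu.out")
        self.trunk_d = ResidualMLP(rng, STATE_DIM, width, n_layers, name="mm.d.trunk")
        self.head_d = Linear(rng, width, 4, name="mm.d.out")
        self.trunk_u = ResidualMLP(rng, STATE_DIM, width, n_layers, name="mm.u.trunk")
        self.head_u = Linear(rng, width, 4, name="mm.u.out")

    def parameters(self):
        for m in (self.trunk_mu, self.head_mu, self.trunk_d, self.head_d,
                  self.trunk_u, self.head_u):
            yield from m.parameters()

    def zero_grad(self):
        for m in (self.trunk_mu, self.head_mu, self.trunk_d, self.head_d,
                  self.trunk_u, self.head_u):
            m.zero_grad()

    def state_dict(self):
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, sd):
        for name, p, _ in self.parameters():
            np.copyto(p, sd[name])

    def copy_from(self, other: "MetaModel"):
        for (_, p, _), (_, q, _) in zip(self.parameters(), other.parameters()):
            np.copyto(p, q)

    # -- forward ----------------------------------------------------------
    def raw_outputs(self, s: np.ndarray, caches: dict | None = None):
        """(mu, d_raw, u) for states (N, 4); d = softplus(d_raw)."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        out = {}
        for name, trunk, head in (
            ("mu", self.trunk_mu, self.head_mu),
            ("d", self.trunk_d, self.head_d),
            ("u", self.trunk_u, self.head_u),
        ):
            cache: list = []
            h = trunk.forward(s, cache)
            out[name] = head.forward(h)
            if caches is not None:
                caches[name] = (cache, h)
        return out["mu"], out["d"], out["u"]

    def outputs(self, s: np.ndarray):
        """(mu (N,4), d (N,4) positive, H (N,4,4)) for states s."""
        mu, d_raw, u = self.raw_outputs(s)
        return mu, softplus(d_raw), _householder_batch(u)

    def predict(self, s) -> GaussianBelief:
        mu, d, H = self.outputs(np.atleast_2d(np.asarray(s, dtype=float)))
        cov = np.einsum("nij,nj,nkj->nik", H, d, H)
        return GaussianBelief(mu[0], cov[0])

    # -- devaluation loss -------------------------------------------------
    def kl_values(self, mu_p, cov_p, s) -> np.ndarray:
        """Per-sample KL(P(.|a,s) || Q(.|s)) with no gradient bookkeeping."""
        mu, d, H = self.outputs(s)
        return gaussian_kl_diag_q(mu_p, cov_p, mu, d, H)

    def kl_backward(self, mu_p, cov_p, s, weights=None) -> float:
        """Accumulate d(weighted mean KL)/dpsi; returns the weighted mean KL.

        The forward-model belief (mu_p, cov_p) is treated as a constant:
        gradients flow to psi only, as required for the devaluation update.
        """
        s = np.atleast_2d(np.asarray(s, dtype=float))
        mu_p = np.atleast_2d(np.asarray(mu_p, dtype=float))
        cov_p = np.asarray(cov_p, dtype=float).reshape(-1, 4, 4)
        n = s.shape[0]
        if weights is None:
            w = np.full(n, 1.0 / n)
        else:
            w = np.asarray(weights, dtype=float)
        caches: dict = {}
        mu, d_raw, u = self.raw_outputs(s, caches)
        d = softplus(d_raw) + KL_JITTER
        H = _householder_batch(u)

        delta = mu - mu_p  # (N, 4)
        M = cov_p + np.einsum("ni,nj->nij", delta, delta)
        HMH = np.einsum("...ki,...kl,...lj->...ij", H, M, H)
        diagHMH = np.einsum("nii->ni", HMH)
        sign, logdet_p = np.linalg.slogdet(cov_p)
        kl = 0.5 * (
            np.sum(diagHMH / d, axis=1)
            + np.sum(np.log(d), axis=1)
            - 4.0
            - logdet_p
        )
        total = float(np.sum(w * kl))

        # gradients w.r.t. the raw head outputs
        Sq_inv = np.einsum("nij,nj,nkj->nik", H, 1.0 / d, H)
        g_mu = np.einsum("nij,nj->ni", Sq_inv, delta) * w[:, None]
        g_d = 0.5 * (1.0 / d - diagHMH / d**2) * w[:, None]
        g_draw = g_d * sigmoid(d_raw)
        # dKL/dH = 0.5 (M H D^-1 + D^-1 H M); chain through H(u)
        MHDinv = np.einsum("nij,njk,nk->nik", M, H, 1.0 / d)
        Gh = 0.5 * (MHDinv + np.swapaxes(MHDinv, 1, 2))
        norm_u = np.linalg.norm(u, axis=1, keepdims=True)
        nvec = u / norm_u
        Gn = -2.0 * np.einsum("nij,nj->ni", Gh + np.swapaxes(Gh, 1, 2), nvec)
        g_u = (Gn - nvec * np.einsum("ni,ni->n", nvec, Gn)[:, None]) / norm_u
        g_u = g_u * w[:, None]

        for g, (cache, h), trunk, head in (
            (g_mu, caches["mu"], self.trunk_mu, self.head_mu),
            (g_draw, caches["d"], self.trunk_d, self.head_d),
            (g_u, caches["u"], self.trunk_u, self.head_u),
        ):
            gh = head.backward(h, g)
            trunk.backward(cache, gh)
        return total


def devaluation_objective(a, s, fm: ForwardModel, mm: MetaModel) -> float:
    """L_mm = KL(P(S'|a,s; theta) || Q(S'|s; psi)) for a single (a, s)."""
    p = fm.predict(s, a)
    q = mm.predict(s)
    return gaussian_kl(p, q)
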