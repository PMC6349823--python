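"""Behavioural metrics and statistical comparison harness.

Coverage Rate (CR) and Coverage Entropy (CE) summarise exploration on a
50x50 positional grid (velocities ignored).  CR(t) is the fraction of cells
visited at least once up to t — monotone, 1/2500 for a stationary agent.  CE
starts from a uniform Laplace counter (one phantom count per cell, so CE(0)
is exactly the maximum ln 2500 nats) and tracks the entropy of the
normalised visit counter: perseveration concentrates the counter and drives
CE down.

Also here: the numerical check of the information decomposition

    E_pi KL(P_a || Q)  =  I(S';A | s)  +  KL(P_mix || Q),

where P_mix is the policy-marginal next-state mixture — the identity that
formalises "seek mutual information, flee the comfort zone" — and the
Mann-Whitney harness used for multi-run comparisons.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .belief import gaussian_kl_diag_q
from .env import ACTIONS

__all__ = [
    "GRID_N",
    "CoverageTracker",
    "coverage_rate",
    "coverage_entropy",
    "mi_kl_decomposition",
    "compare_runs",
]

GRID_N = 50
N_CELLS = GRID_N * GRID_N
MAX_ENTROPY = np.log(N_CELLS)


def _cells(positions: np.ndarray) -> np.ndarray:
    """Map positions in [0,1]^2 to flat cell indices; the top edge closes."""
    p = np.atleast_2d(np.asarray(positions, dtype=float))
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("positions must lie in the unit square")
    ij = np.minimum((p * GRID_N).astype(int), GRID_N - 1)
    return ij[:, 0] * GRID_N + ij[:, 1]


class CoverageTracker:
    """Incremental CR/CE bookkeeping over a stream of positions."""

    def __init__(self):
        self.visited = np.zeros(N_CELLS, dtype=bool)
        self.counts = np.ones(N_CELLS)  # Laplace init: CE starts maximal
        self.n_visited = 0
        self._sum_nlogn = 0.0  # sum n_i log n_i (log 1 = 0 initially)
        self._total = float(N_CELLS)
        self.cr_series: list[float] = []
        self.ce_series: list[float] = []

    def update(self, position) -> None:
        c = int(_cells(position)[0])
        if not self.visited[c]:
            self.visited[c] = True
            self.n_visited += 1
        old = self.counts[c]
        self._sum_nlogn += (old + 1.0) * np.log(old + 1.0) - old * np.log(old)
        self.counts[c] = old + 1.0
        self._total += 1.0
        self.cr_series.append(self.n_visited / N_CELLS)
        self.ce_series.append(np.log(self._total) - self._sum_nlogn / self._total)

    @property
    def coverage_rate(self) -> float:
        return self.n_visited / N_CELLS

    @property
    def coverage_entropy(self) -> float:
        return float(np.log(self._total) - self._sum_nlogn / self._total)


def coverage_rate(positions: np.ndarray) -> np.ndarray:
    """CR series for a whole trajectory of positions (T, 2)."""
    cells = _cells(positions)
    seen = np.zeros(N_CELLS, dtype=bool)
    out = np.empty(len(cells))
    n = 0
    for i, c in enumerate(cells):
        if not seen[c]:
            seen[c] = True
            n += 1
        out[i] = n / N_CELLS
    return out


def coverage_entropy(positions: np.ndarray) -> np.ndarray:
    """CE series (nats) for a trajectory; CE before any visit is ln 2500."""
    cells = _cells(positions)
    counts = np.ones(N_CELLS)
    s = 0.0
    total = float(N_CELLS)
    out = np.empty(len(cells))
    for i, c in enumerate(cells):
        old = counts[c]
        s += (old + 1.0) * np.log(old + 1.0) - old * np.log(old)
        counts[c] = old + 1.0
        total += 1.0
        out[i] = np.log(total) - s / total
    return out


def _gaussian_logpdfs(x: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """log N(x | mean_m, cov_m) for samples x (n,4) and components (M,4[,4])."""
    M = means.shape[0]
    n = x.shape[0]
    out = np.empty((n, M))
    k = x.shape[1]
    for m in range(M):
        L = np.linalg.cholesky(covs[m])
        diff = x - means[m]
        alpha = np.linalg.solve(L, diff.T)
        maha = np.sum(alpha * alpha, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, m] = -0.5 * (k * np.log(2 * np.pi) + logdet + maha)
    return out


def mi_kl_decomposition(s, fm, mm, pp, n_samples: int = 100_000,
                        rng: np.random.Generator | None = None):
    """Monte-Carlo check of E_pi KL(P_a||Q) = I(S';A|s) + KL(P_mix||Q).

    Returns (lhs, mi_term, kl_term, se) where ``lhs`` is the closed-form
    policy-averaged KL from forward-model beliefs to the meta-model, and the
    mutual-information and mixture-KL terms are estimated from ``n_samples``
    joint draws (a, s') with shared samples.  ``se`` is the Monte-Carlo
    standard error of the summed estimate mi + kl.
    """
    if rng is None:
        rng = np.random.default_rng()
    s = np.atleast_1d(np.asarray(s, dtype=float))
    pi = pp.distribution(s)
    mu_all, cov_all = fm.predict_all_actions(s[None, :], ACTIONS.accelerations)
    means, covs = mu_all[0], cov_all[0]  # (121, 4), (121, 4, 4)
    mu_q, d_q, H_q = mm.outputs(s[None, :])

    # closed-form lhs
    per_action_kl = gaussian_kl_diag_q(
        means, covs, np.broadcast_to(mu_q, means.shape),
        np.broadcast_to(d_q, means.shape),
        np.broadcast_to(H_q, covs.shape),
    )
    lhs = float(np.sum(pi * per_action_kl))

    # joint samples (a_i, x_i); x marginally follows the policy mixture
    acts = rng.choice(len(pi), size=n_samples, p=pi)
    chols = np.linalg.cholesky(covs)
    z = rng.standard_normal((n_samples, 4))
    x = means[acts] + np.einsum("nij,nj->ni", chols[acts], z)

    logp_comp = _gaussian_logpdfs(x, means, covs)  # (n, 121)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
    logp_mix = _logsumexp(logp_comp + log_pi[None, :], axis=1)
    logp_own = logp_comp[np.arange(n_samples), acts]

    cov_q = np.einsum("ij,j,kj->ik", H_q[0], d_q[0], H_q[0])
    logq = _gaussian_logpdfs(x, mu_q[None, 0], cov_q[None])[:, 0]

    mi_samples = logp_own - logp_mix
    kl_samples = logp_mix - logq
    mi_term = float(np.mean(mi_samples))
    kl_term = float(np.mean(kl_samples))
    total = mi_samples + kl_samples
    se = float(np.std(total, ddof=1) / np.sqrt(n_samples))
    return lhs, mi_term, kl_term, se


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


def compare_runs(scores_a, scores_b, alpha: float = 0.025):
    """One-sided Mann-Whitney U test of H1: scores_a < scores_b.

    Returns (U, p).  ``alpha`` is the Bonferroni-corrected level used in the
    planned two-comparison design; ties are handled with midranks.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two scores per group")
    res = stats.mannwhitneyu(a, b, alternative="less")
    return float(res.statistic), float(res.pvalue)
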