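"""Categorical action policy and state-value function.

The policy network maps a state to 121 logits — a categorical distribution
over the 11x11 acceleration grid.  The value network shares the same trunk
architecture with a scalar head; a frozen target copy stabilises fitted
policy evaluation (the Bellman target y = R + gamma * v(s'; target) treats
the target network as a constant).

Two policy objectives are provided:

* the exact value-gradient objective — the expectation over actions in
  L = -E_a[ R(a,s) + gamma * v(s'_a) ] is enumerated over all 121 actions
  (discrete actions make the enumeration exact and cheap; the next state is
  the forward model's mean because the environment is deterministic);
* REINFORCE, -mean[log pi(a|s) * R], for the pruned variants that keep an
  action policy but no value function.

Gradients flow to the policy parameters only; rewards, values and
forward-model outputs enter as constants.
"""

from __future__ import annotations

import numpy as np

from .nets import Linear, ResidualMLP
from .env import N_ACTIONS

__all__ = ["PolicyNetwork", "ValueNetwork", "softmax", "policy_entropy"]

STATE_DIM = 4


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def policy_entropy(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of categorical distributions along the last axis."""
    p = np.clip(probs, 1e-300, None)
    return -np.sum(p * np.log(p), axis=-1)


class _HeadedNet:
    def __init__(self, rng, d_out, width, n_layers, name):
        self.trunk = ResidualMLP(rng, STATE_DIM, width, n_layers, name=f"{name}.trunk")
        self.head = Linear(rng, width, d_out, name=f"{name}.out")

    def parameters(self):
        yield from self.trunk.parameters()
        yield from self.head.parameters()

    def zero_grad(self):
        self.trunk.zero_grad()
        self.head.zero_grad()

    def state_dict(self):
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, sd):
        for name, p, _ in self.parameters():
            np.copyto(p, sd[name])

    def copy_from(self, other):
        for (_, p, _), (_, q, _) in zip(self.parameters(), other.parameters()):
            np.copyto(p, q)

    def forward(self, s: np.ndarray, cache: list | None = None) -> np.ndarray:
        s = np.atleast_2d(np.asarray(s, dtype=float))
        h = self.trunk.forward(s, cache)
        out = self.head.forward(h)
        if cache is not None:
            cache.append(h)
        return out

    def backward_from_output(self, cache: list, g_out: np.ndarray) -> None:
        h = cache.pop()
        gh = self.head.backward(h, g_out)
        self.trunk.backward(cache, gh)


class PolicyNetwork(_HeadedNet):
    """pi(A|s; phi): four ReLU layers + residual, linear head to 121 logits."""

    def __init__(self, rng: np.random.Generator, width: int = 512, n_layers: int = 4):
        super().__init__(rng, N_ACTIONS, width, n_layers, name="pi")

    def distribution(self, s) -> np.ndarray:
        """Softmax action probabilities, shape (N, 121) (or (121,) for one state)."""
        single = np.asarray(s).ndim == 1
        p = softmax(self.forward(s))
        return p[0] if single else p

    def sample(self, s, rng: np.random.Generator) -> int:
        p = self.distribution(np.atleast_1d(np.asarray(s, dtype=float)))
        p = p if p.ndim == 1 else p[0]
        return int(rng.choice(N_ACTIONS, p=p))

    # -- objectives -------------------------------------------------------
    def value_gradient_backward(self, s: np.ndarray, returns: np.ndarray) -> float:
        """Exact-enumeration policy objective L = -mean_n sum_a pi_a G_na.

        ``returns`` (N, 121) holds the per-action return R(a,s) + gamma*v(s'_a)
        computed by the caller with every non-policy model frozen.  Accumulates
        dL/dphi and returns the scalar loss.
        """
        s = np.atleast_2d(np.asarray(s, dtype=float))
        G = np.asarray(returns, dtype=float)
        n = s.shape[0]
        cache: list = []
        logits = self.forward(s, cache)
        pi = softmax(logits)
        loss = -float(np.mean(np.sum(pi * G, axis=1)))
        Gbar = np.sum(pi * G, axis=1, keepdims=True)
        g_logits = -(pi * (G - Gbar)) / n
        self.backward_from_output(cache, g_logits)
        return loss

    def reinforce_backward(self, s: np.ndarray, actions: np.ndarray,
                           rewards: np.ndarray) -> float:
        """REINFORCE loss -mean[log pi(a|s) * R]; accumulates dL/dphi."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        actions = np.atleast_1d(np.asarray(actions, dtype=int))
        R = np.atleast_1d(np.asarray(rewards, dtype=float))
        n = s.shape[0]
        cache: list = []
        logits = self.forward(s, cache)
        pi = softmax(logits)
        logp = np.log(np.clip(pi[np.arange(n), actions], 1e-300, None))
        loss = -float(np.mean(logp * R))
        g_logits = pi * (R / n)[:, None]
        g_logits[np.arange(n), actions] -= R / n
        self.backward_from_output(cache, g_logits)
        return loss


class ValueNetwork(_HeadedNet):
    """v(s; nu): same trunk architecture, scalar head."""

    def __init__(self, rng: np.random.Generator, width: int = 512, n_layers: int = 4):
        super().__init__(rng, 1, width, n_layers, name="v")

    def values(self, s) -> np.ndarray:
        return self.forward(s)[:, 0]

    def bellman_backward(self, s: np.ndarray, targets: np.ndarray) -> float:
        """Mean squared Bellman residual ||y - v(s)||^2 with y constant."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        y = np.atleast_1d(np.asarray(targets, dtype=float))
        n = s.shape[0]
        cache: list = []
        v = self.forward(s, cache)[:, 0]
        resid = v - y
        loss = float(np.mean(resid * resid))
        g = (2.0 * resid / n)[:, None]
        self.backward_from_output(cache, g)
        return loss


def bellman_targets(rewards: np.ndarray, s_next: np.ndarray, target_net: ValueNetwork,
                    gamma: float) -> np.ndarray:
    """y = R + gamma * v(s'; target); the target network sees no gradients."""
    return np.asarray(rewards, dtype=float) + gamma * target_net.values(s_next)
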