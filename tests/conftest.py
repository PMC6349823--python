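import numpy as np
import pytest

from hhvg.belief import ForwardModel, MetaModel
from hhvg.env import EnvConfig
from hhvg.policy import PolicyNetwork, ValueNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def env_config():
    return EnvConfig()


@pytest.fixture
def small_fm(rng):
    return ForwardModel(rng, width=16)


@pytest.fixture
def small_mm(rng):
    return MetaModel(rng, width=16)


@pytest.fixture
def small_policy(rng):
    return PolicyNetwork(rng, width=16)


@pytest.fixture
def small_value(rng):
    return ValueNetwork(rng, width=16)


def finite_difference_check(model, run_backward, loss_value, n_probes=8, eps=1e-6,
                            seed=1):
    """Max relative error between accumulated grads and central differences."""
    model.zero_grad()
    run_backward()
    triples = list(model.parameters())
    probe_rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_probes):
        name, p, g = triples[probe_rng.integers(len(triples))]
        idx = tuple(probe_rng.integers(d) for d in p.shape)
        orig = p[idx]
        p[idx] = orig + eps
        lp = loss_value()
        p[idx] = orig - eps
        lm = loss_value()
        p[idx] = orig
        fd = (lp - lm) / (2 * eps)
        errs.append(abs(fd - g[idx]) / max(1e-8, abs(fd), abs(g[idx])))
    return max(errs)
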