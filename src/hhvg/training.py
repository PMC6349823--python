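"""Run orchestration: the data-accumulation phase and the pruning hierarchy.

An agent lives one episode: a Data Accumulation Phase (DAP) of ``t_dap``
environment steps during which it acts, stores every transition in a replay
database and trains its components once per step, followed (optionally) by an
action-free post-DAP stage of forward-model-only refinement on the frozen
buffer with a plateau learning-rate schedule.

The pruning hierarchy defines six variants by progressively removing
components (forward model FM, action policy AP, intrinsic reward IR, value
function VF, meta-model MM):

========  ==================================================================
C/B       full agent: devaluation progress reward, value function, exact
          value-gradient policy updates
C/PE      meta-model removed; reward is forward-model learning progress
PG/IRS    value function removed; rewards replayed from a recorded C/B run,
          standard policy gradients
PG/GR     as PG/IRS but with time-invariant N(0, 0.01^2) surrogate rewards
P/RW      forward model only; uniform random policy (epsilon-greedy, eps=1)
Oracle    forward model only, trained on the oracle grid dataset (no
          environment interaction; see :mod:`hhvg.oracle`)
========  ==================================================================

All variants sharing a component draw its initial weights from the same
seeded stream, so one experiment's variants start from identical
environments, initial positions and (where architectures coincide) network
initialisations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import env as envmod
from .belief import ForwardModel, MetaModel
from .env import ACTIONS, EnvConfig, N_ACTIONS
from .metrics import CoverageTracker
from .nets import Adam
from .oracle import PlateauScheduler
from .policy import PolicyNetwork, ValueNetwork, bellman_targets
from .rewards import RewardDatabase, replay_reward, surrogate_reward

__all__ = [
    "VariantSpec",
    "RunConfig",
    "ReplayBuffer",
    "Agent",
    "make_variant",
    "dap_step",
    "run_dap",
    "run_post_dap",
    "RunResult",
    "VARIANTS",
]

# Component flags per pruning-hierarchy column; "partial" marks a component
# that is present in degraded form (uniform policy, replayed rewards).
VARIANTS: dict[str, dict[str, str]] = {
    "Oracle": dict(FM="on", AP="off", IR="off", VF="off", MM="off"),
    "P/RW": dict(FM="on", AP="partial", IR="off", VF="off", MM="off"),
    "PG/GR": dict(FM="on", AP="on", IR="off", VF="off", MM="off"),
    "PG/IRS": dict(FM="on", AP="on", IR="partial", VF="off", MM="off"),
    "C/PE": dict(FM="on", AP="on", IR="on", VF="on", MM="off"),
    "C/B": dict(FM="on", AP="on", IR="on", VF="on", MM="on"),
}


@dataclass(frozen=True)
class VariantSpec:
    name: str
    FM: str
    AP: str
    IR: str
    VF: str
    MM: str

    @classmethod
    def of(cls, name: str) -> "VariantSpec":
        if name not in VARIANTS:
            raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
        return cls(name=name, **VARIANTS[name])

    @property
    def has_policy_net(self) -> bool:
        return self.AP == "on"

    @property
    def has_value(self) -> bool:
        return self.VF == "on"

    @property
    def has_meta(self) -> bool:
        return self.MM == "on"


@dataclass
class RunConfig:
    """Hyperparameters of one run; defaults are the full-scale conditions."""

    t_dap: int = 30_000
    t_post: int = 30_000
    seed: int = 0
    batch_size: int = 128
    policy_batch: int = 32  # sub-batch for the 121-action enumeration
    width: int = 512
    lr_model: float = 1e-4
    lr_policy: float = 1e-4
    gamma: float = 0.9
    target_sync: int = 100
    plateau_patience: int = 3000
    plateau_factor: float = 0.1
    sigma_s: float = 0.01
    replay_capacity: int | None = None
    policy_optimizer: str = "sgd"  # plain SGD keeps reward magnitudes meaningful

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class ReplayBuffer:
    """Append-only transition store (t, s, a_index, s'); optional FIFO cap."""

    def __init__(self, capacity: int | None = None):
        self.capacity = capacity
        self.t: list[int] = []
        self.s: list[np.ndarray] = []
        self.a: list[int] = []
        self.s_next: list[np.ndarray] = []

    def append(self, t: int, s: np.ndarray, a: int, s_next: np.ndarray) -> None:
        self.t.append(int(t))
        self.s.append(np.asarray(s, dtype=float))
        self.a.append(int(a))
        self.s_next.append(np.asarray(s_next, dtype=float))
        if self.capacity is not None and len(self.t) > self.capacity:
            for lst in (self.t, self.s, self.a, self.s_next):
                lst.pop(0)

    def __len__(self) -> int:
        return len(self.t)

    def sample(self, batch_size: int, rng: np.random.Generator):
        """Uniform sample without replacement (whole buffer if smaller)."""
        n = len(self)
        take = min(batch_size, n)
        idx = rng.choice(n, size=take, replace=False)
        s = np.array([self.s[i] for i in idx])
        a_idx = np.array([self.a[i] for i in idx], dtype=int)
        s_next = np.array([self.s_next[i] for i in idx])
        return s, a_idx, s_next

    def arrays(self):
        return (
            np.array(self.t, dtype=int),
            np.array(self.s),
            np.array(self.a, dtype=int),
            np.array(self.s_next),
        )

    def to_frame(self):
        import pandas as pd

        t, s, a, sn = self.arrays()
        return pd.DataFrame(
            {
                "t": t,
                "x": s[:, 0], "y": s[:, 1], "vx": s[:, 2], "vy": s[:, 3],
                "action_index": a,
                "x_next": sn[:, 0], "y_next": sn[:, 1],
                "vx_next": sn[:, 2], "vy_next": sn[:, 3],
            }
        )


def _component_rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# spawn keys: stable identity of each random stream across variants
_K_FM, _K_MM, _K_POLICY, _K_VALUE, _K_ACT, _K_BATCH, _K_REWARD = range(7)


class Agent:
    """Wired components of one variant plus their optimizers."""

    def __init__(self, spec: VariantSpec, run_config: RunConfig,
                 reward_db: RewardDatabase | None = None):
        self.spec = spec
        self.cfg = run_config
        seed = run_config.seed
        w = run_config.width
        self.fm = ForwardModel(_component_rng(seed, _K_FM), width=w,
                               sigma_s=run_config.sigma_s)
        self.opt_fm = Adam(self.fm.parameters(), lr=run_config.lr_model)
        self.mm = self.mm_shadow = self.opt_mm = None
        self.policy = self.opt_policy = None
        self.value = self.value_target = self.opt_value = None
        self.replay_db: RewardDatabase | None = None
        if spec.has_meta:
            self.mm = MetaModel(_component_rng(seed, _K_MM), width=w, n_layers=3)
            self.mm_shadow = MetaModel(_component_rng(seed, _K_MM), width=w, n_layers=3)
            self.opt_mm = Adam(self.mm.parameters(), lr=run_config.lr_model)
        if spec.has_policy_net:
            self.policy = PolicyNetwork(_component_rng(seed, _K_POLICY), width=w)
            if run_config.policy_optimizer == "sgd":
                from .nets import SGD

                self.opt_policy = SGD(self.policy.parameters(), lr=run_config.lr_policy)
            else:
                self.opt_policy = Adam(self.policy.parameters(), lr=run_config.lr_policy)
        if spec.has_value:
            self.value = ValueNetwork(_component_rng(seed, _K_VALUE), width=w)
            self.value_target = ValueNetwork(_component_rng(seed, _K_VALUE), width=w)
            self.value_target.copy_from(self.value)
            self.opt_value = Adam(self.value.parameters(), lr=run_config.lr_model)
        if spec.IR == "partial":  # PG/IRS replays a recorded reward database
            if reward_db is None or len(reward_db) == 0:
                raise ValueError(
                    f"variant {spec.name} requires a populated RewardDatabase "
                    "from a prior C/B run"
                )
            self.replay_db = reward_db
        # C/PE compares forward-model loss before/after each update
        self._fm_before = None
        if spec.name == "C/PE":
            self._fm_before = ForwardModel(_component_rng(seed, _K_FM), width=w,
                                           sigma_s=run_config.sigma_s)

    def select_action(self, s: np.ndarray, rng: np.random.Generator) -> int:
        if self.spec.AP == "partial" or self.policy is None:
            return int(rng.integers(N_ACTIONS))
        return self.policy.sample(s, rng)


def make_variant(name: str, run_config: RunConfig,
                 reward_db: RewardDatabase | None = None) -> Agent:
    """Instantiate a pruning-hierarchy variant with seeded initialisation."""
    return Agent(VariantSpec.of(name), run_config, reward_db=reward_db)


def dap_step(agent: Agent, state: np.ndarray, t: int, buffer: ReplayBuffer,
             env_config: EnvConfig, rng_act: np.random.Generator,
             rng_batch: np.random.Generator, rng_reward: np.random.Generator,
             reward_log: RewardDatabase | None = None,
             step_counter: list | None = None) -> tuple[np.ndarray, dict]:
    """One interactive step: act, store, and update each active component.

    Fixed order: action selection, environment step, buffer append, batch
    sampling, forward-model update, meta-model update (+ devaluation
    progress), reward computation, value update, policy update.
    """
    spec = agent.spec
    cfg = agent.cfg
    logs: dict = {"t": t}

    a_idx = agent.select_action(state, rng_act)
    s_next = envmod.step(state, a_idx, env_config)
    buffer.append(t, state, a_idx, s_next)

    bs, ba_idx, bs_next = buffer.sample(cfg.batch_size, rng_batch)
    ba = ACTIONS.accelerations[ba_idx]

    # forward model update (every variant)
    if agent._fm_before is not None:
        agent._fm_before.copy_from(agent.fm)
    agent.fm.zero_grad()
    fm_loss = agent.fm.mse_backward(bs, ba, bs_next)
    agent.opt_fm.step()
    logs["fm_loss"] = fm_loss

    rewards = None
    # meta-model (devaluation) update and devaluation progress
    if spec.has_meta:
        mu_p, cov_p = agent.fm.predict_batch(bs, ba)
        kl_before = agent.mm.kl_values(mu_p, cov_p, bs)
        agent.mm_shadow.copy_from(agent.mm)
        agent.mm.zero_grad()
        mm_loss = agent.mm.kl_backward(mu_p, cov_p, bs)
        agent.opt_mm.step()
        kl_after = agent.mm.kl_values(mu_p, cov_p, bs)
        rewards = kl_before - kl_after  # devaluation progress, per transition
        logs["mm_loss"] = mm_loss
        logs["mean_reward"] = float(np.mean(rewards))
        if reward_log is not None:
            reward_log.append(t, rewards)
    elif spec.name == "C/PE":
        before = agent._fm_before.mse_losses(bs, ba, bs_next)
        after = agent.fm.mse_losses(bs, ba, bs_next)
        rewards = before - after  # learning progress, per transition
        logs["mean_reward"] = float(np.mean(rewards))
    elif spec.IR == "partial":
        rewards = np.array([replay_reward(agent.replay_db, t, rng_reward)])
        logs["mean_reward"] = float(rewards[0])
    elif spec.name == "PG/GR":
        rewards = np.array([surrogate_reward(rng_reward)])
        logs["mean_reward"] = float(rewards[0])

    # value update (fitted policy evaluation with frozen target)
    if spec.has_value:
        y = bellman_targets(rewards, bs_next, agent.value_target, cfg.gamma)
        agent.value.zero_grad()
        v_loss = agent.value.bellman_backward(bs, y)
        agent.opt_value.step()
        logs["value_loss"] = v_loss
        if step_counter is not None:
            step_counter[0] += 1
            if step_counter[0] % cfg.target_sync == 0:
                agent.value_target.copy_from(agent.value)

    # policy update
    if spec.has_policy_net:
        if spec.has_value:  # exact value-gradient objective (C/B, C/PE)
            sp = bs[: cfg.policy_batch]
            mu_all, cov_all = agent.fm.predict_all_actions(
                sp, ACTIONS.accelerations, with_cov=spec.has_meta
            )
            n, m = mu_all.shape[:2]
            if spec.has_meta:
                mu_q0, d_q0, H_q0 = agent.mm_shadow.outputs(sp)
                mu_q1, d_q1, H_q1 = agent.mm.outputs(sp)
                from .belief import gaussian_kl_diag_q

                def expand(arr):
                    return np.broadcast_to(arr[:, None], (n, m) + arr.shape[1:])

                kl0 = gaussian_kl_diag_q(mu_all, cov_all, expand(mu_q0),
                                         expand(d_q0), expand(H_q0))
                kl1 = gaussian_kl_diag_q(mu_all, cov_all, expand(mu_q1),
                                         expand(d_q1), expand(H_q1))
                r_all = kl0 - kl1  # devaluation progress per candidate action
            else:
                r_all = np.zeros((n, m))
            v_next = agent.value.forward(mu_all.reshape(-1, 4))[:, 0].reshape(n, m)
            returns = r_all + cfg.gamma * v_next
            agent.policy.zero_grad()
            p_loss = agent.policy.value_gradient_backward(sp, returns)
        else:  # REINFORCE on the current transition (PG/IRS, PG/GR)
            agent.policy.zero_grad()
            p_loss = agent.policy.reinforce_backward(
                np.atleast_2d(state), [a_idx], rewards[:1]
            )
        agent.opt_policy.step()
        logs["policy_loss"] = p_loss
        from .policy import policy_entropy

        logs["policy_entropy"] = float(policy_entropy(agent.policy.distribution(state)))

    logs["action"] = a_idx
    return s_next, logs


@dataclass
class RunResult:
    """Outcome of one run: models, data, coverage and per-step logs."""

    spec: VariantSpec
    config: RunConfig
    agent: Agent
    buffer: ReplayBuffer
    coverage: CoverageTracker
    reward_db: RewardDatabase | None
    logs: list = field(default_factory=list)
    post_logs: dict | None = None

    def logs_frame(self):
        import pandas as pd

        return pd.DataFrame(self.logs)

    def summary(self) -> str:
        lines = [
            f"variant            {self.spec.name}",
            f"steps (DAP)        {len(self.buffer)}",
            f"coverage rate      {self.coverage.coverage_rate:.4f}",
            f"coverage entropy   {self.coverage.coverage_entropy:.4f} nats",
        ]
        if self.logs:
            lines.append(f"final fm loss      {self.logs[-1]['fm_loss']:.6f}")
        if self.post_logs is not None:
            lines.append(f"post-DAP epochs    {len(self.post_logs['train_loss'])}")
        return "\n".join(lines)


def run_dap(variant: str, env_config: EnvConfig, run_config: RunConfig,
            reward_db: RewardDatabase | None = None,
            log_every: int = 1) -> RunResult:
    """Run the Data Accumulation Phase for one variant from reset().

    Fully reproducible from ``run_config.seed``.  For the full agent the
    per-step devaluation-progress samples are recorded into a
    :class:`RewardDatabase` for later PG/IRS replay.
    """
    agent = make_variant(variant, run_config, reward_db=reward_db)
    seed = run_config.seed
    rng_act = _component_rng(seed, _K_ACT)
    rng_batch = _component_rng(seed, _K_BATCH)
    rng_reward = _component_rng(seed, _K_REWARD)
    buffer = ReplayBuffer(capacity=run_config.replay_capacity)
    coverage = CoverageTracker()
    out_db = RewardDatabase() if agent.spec.has_meta else None
    state = envmod.reset(env_config)
    coverage.update(state[:2])
    logs = []
    counter = [0]
    for t in range(run_config.t_dap):
        state, step_logs = dap_step(
            agent, state, t, buffer, env_config, rng_act, rng_batch, rng_reward,
            reward_log=out_db, step_counter=counter,
        )
        coverage.update(state[:2])
        if t % log_every == 0:
            logs.append(step_logs)
    return RunResult(agent.spec, run_config, agent, buffer, coverage, out_db, logs)


def run_post_dap(result: RunResult, epochs: int | None = None) -> dict:
    """Action-free refinement: forward-model-only training on the frozen buffer.

    The plateau schedule monitors the training batch loss (the agent owns no
    oracle test set).  No environment interaction occurs.  Returns the loss
    curve and records it on ``result.post_logs``.
    """
    cfg = result.config
    if epochs is None:
        epochs = cfg.t_post
    if len(result.buffer) == 0:
        raise ValueError("replay buffer is empty; run the DAP first")
    rng = _component_rng(cfg.seed, _K_BATCH + 100)
    agent = result.agent
    sched = PlateauScheduler(agent.opt_fm, factor=cfg.plateau_factor,
                             patience=cfg.plateau_patience)
    losses = []
    n_before = len(result.buffer)
    for _ in range(epochs):
        bs, ba_idx, bs_next = result.buffer.sample(cfg.batch_size, rng)
        agent.fm.zero_grad()
        loss = agent.fm.mse_backward(bs, ACTIONS.accelerations[ba_idx], bs_next)
        agent.opt_fm.step()
        sched.step(loss)
        losses.append(loss)
    assert len(result.buffer) == n_before  # buffer frozen during post-DAP
    result.post_logs = {"train_loss": np.array(losses),
                        "lr_reductions": sched.reductions}
    return result.post_logs
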