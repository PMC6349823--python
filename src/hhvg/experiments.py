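"""Packaged experiments: the ablation benchmark and the collapse diagnostic.

These are the study designs the package exists to run, wired end to end:

* :func:`run_ordering_experiment` — the scaled-down ablation benchmark.  Each
  seed runs every interactive variant (C/B first, so its recorded rewards can
  be replayed by PG/IRS) plus an Oracle trained on the grid dataset, then
  scores every forward model on one shared validation split.  Desk-scale
  conditions: 2,000 DAP steps, width-64 networks, a 5x5 x 3x3 x 5x5 oracle
  grid and a constant learning rate of 1e-3 (short runs need a larger
  constant rate than the full-scale default of 1e-4).
* :func:`policy_collapse_experiment` — the homeostatic/heterostatic
  dichotomy on a frozen state: rewarding the devaluation objective itself
  (interestingness seeking) collapses the policy to a point mass, while
  rewarding devaluation *progress* leaves the policy spread out under the
  identical alternating update schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .belief import ForwardModel, MetaModel, gaussian_kl_diag_q
from .env import ACTIONS, EnvConfig
from .nets import Adam, SGD
from .oracle import (
    OracleGridSpec,
    error_percentage,
    generate_oracle_dataset,
    max_pairwise_distance,
    split_dataset,
    train_oracle,
    validation_mse,
)
from .policy import PolicyNetwork, policy_entropy
from .training import RunConfig, run_dap, run_post_dap

__all__ = [
    "desk_scale_config",
    "desk_scale_grid",
    "run_ordering_experiment",
    "policy_collapse_experiment",
]

INTERACTIVE_VARIANTS = ("C/B", "C/PE", "PG/IRS", "PG/GR", "P/RW")


def desk_scale_config(seed: int, t_dap: int = 2000, width: int = 64,
                      t_post: int = 3000) -> RunConfig:
    """Scaled-down run conditions used throughout the desk-scale benchmark."""
    return RunConfig(
        t_dap=t_dap,
        t_post=t_post,
        seed=seed,
        batch_size=128,
        policy_batch=32,
        width=width,
        lr_model=1e-3,
        lr_policy=0.3,
    )


def desk_scale_grid() -> OracleGridSpec:
    return OracleGridSpec(n_pos=(5, 5), n_vel=(3, 3), n_act=(5, 5))


def run_ordering_experiment(seed: int, n_seeds: int = 3, t_dap: int = 2000,
                            width: int = 64, t_post: int = 3000,
                            oracle_epochs: int = 4000,
                            env_config: EnvConfig | None = None,
                            grid: OracleGridSpec | None = None,
                            variants=INTERACTIVE_VARIANTS,
                            include_oracle: bool = True,
                            progress: bool = False) -> pd.DataFrame:
    """Run the ablation ladder across seeds and benchmark every variant.

    Each interactive run is a DAP of ``t_dap`` steps followed by ``t_post``
    post-DAP refinement epochs on its frozen buffer; forward models are
    scored on the shared validation split at both stages.  Returns a tidy
    DataFrame with one row per (variant, seed): ``variant, seed, mse,
    percent_error`` (terminal, i.e. post-DAP when ``t_post > 0``),
    ``percent_error_dap, coverage_rate, coverage_entropy``.  All variants of
    one seed share the environment, initial position and network
    initialisation.
    """
    env_config = env_config or EnvConfig()
    grid = grid or desk_scale_grid()
    dataset = generate_oracle_dataset(grid, env_config)
    split = split_dataset(len(dataset), seed=seed)
    denom = max_pairwise_distance(dataset.s_next[split.validation])

    def score(fm):
        return (
            validation_mse(fm, dataset, split.validation),
            error_percentage(fm, dataset, split.validation, denominator=denom),
        )

    rows = []
    base = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in base.spawn(n_seeds)]
    for k, run_seed in enumerate(run_seeds):
        cfg = desk_scale_config(run_seed, t_dap=t_dap, width=width, t_post=t_post)
        reward_db = None
        for name in variants:
            if progress:
                print(f"[seed {k}] running {name}")
            db = reward_db if name == "PG/IRS" else None
            res = run_dap(name, env_config, cfg, reward_db=db)
            if name == "C/B":
                reward_db = res.reward_db
            _, pct_dap = score(res.agent.fm)
            if t_post > 0:
                run_post_dap(res)
            mse, pct = score(res.agent.fm)
            rows.append(
                {
                    "variant": name,
                    "seed": run_seed,
                    "mse": mse,
                    "percent_error": pct,
                    "percent_error_dap": pct_dap,
                    "coverage_rate": res.coverage.coverage_rate,
                    "coverage_entropy": res.coverage.coverage_entropy,
                }
            )
        if include_oracle:
            if progress:
                print(f"[seed {k}] training Oracle")
            fm = ForwardModel(
                np.random.default_rng(np.random.SeedSequence(run_seed, spawn_key=(0,))),
                width=width,
            )
            fm, _ = train_oracle(dataset, split, fm, epochs=oracle_epochs,
                                 lr=1e-3, seed=run_seed)
            mse, pct = score(fm)
            rows.append(
                {
                    "variant": "Oracle",
                    "seed": run_seed,
                    "mse": mse,
                    "percent_error": pct,
                    "percent_error_dap": np.nan,
                    "coverage_rate": np.nan,
                    "coverage_entropy": np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CollapseResult:
    """Entropy trajectories of the two alternating-update agents."""

    entropy_interestingness: np.ndarray
    entropy_progress: np.ndarray

    @property
    def final_interestingness(self) -> float:
        return float(self.entropy_interestingness[-1])

    @property
    def final_progress(self) -> float:
        return float(self.entropy_progress[-1])


def _alternating_updates(s: np.ndarray, fm: ForwardModel, mm: MetaModel,
                         pp: PolicyNetwork, n_updates: int, use_progress: bool,
                         lr_policy: float, lr_meta: float) -> np.ndarray:
    """Alternate one psi (devaluation) and one phi (policy) step on a frozen state.

    The policy objective per action is either the devaluation objective
    itself (interestingness seeking) or the devaluation progress.  Policy
    steps use plain gradient descent so that reward *magnitudes* matter, as
    they do in the analysis; the meta-model uses Adam.
    """
    opt_pi = SGD(pp.parameters(), lr=lr_policy)
    opt_mm = Adam(mm.parameters(), lr=lr_meta)
    s2 = s[None, :]
    mu_all, cov_all = fm.predict_all_actions(s2, ACTIONS.accelerations)
    means, covs = mu_all[0], cov_all[0]  # frozen forward model
    srep = np.repeat(s2, len(means), axis=0)
    entropies = np.empty(n_updates)
    for i in range(n_updates):
        pi = pp.distribution(s)
        # psi step: devalue the policy-weighted predicted outcomes
        kl_before = mm.kl_values(means, covs, srep)
        mm.zero_grad()
        mm.kl_backward(means, covs, srep, weights=pi)
        opt_mm.step()
        kl_after = mm.kl_values(means, covs, srep)
        # phi step on the per-action reward
        G = (kl_before - kl_after) if use_progress else kl_after
        pp.zero_grad()
        pp.value_gradient_backward(s2, G[None, :])
        opt_pi.step()
        entropies[i] = policy_entropy(pp.distribution(s))
    return entropies


def policy_collapse_experiment(seed: int, n_updates: int = 2000, width: int = 64,
                               lr_policy: float = 0.5, lr_meta: float = 1e-3,
                               state=None) -> CollapseResult:
    """Run both reward choices from identical initial conditions.

    Returns the two policy-entropy trajectories (nats).  The
    interestingness-seeking agent is expected to collapse toward a point
    mass; the devaluation-progress agent to retain a spread policy.
    """
    if state is None:
        state = np.array([0.5, 0.5, 0.0, 0.0])
    entropies = {}
    for use_progress in (False, True):
        rng = np.random.SeedSequence(seed)
        fm = ForwardModel(np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,))), width=width)
        mm = MetaModel(np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,))), width=width)
        pp = PolicyNetwork(np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,))), width=width)
        entropies[use_progress] = _alternating_updates(
            np.asarray(state, dtype=float), fm, mm, pp, n_updates, use_progress,
            lr_policy, lr_meta,
        )
    return CollapseResult(
        entropy_interestingness=entropies[False],
        entropy_progress=entropies[True],
    )
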