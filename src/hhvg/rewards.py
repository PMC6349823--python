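"""Intrinsic reward constructions for the ablation ladder.

Four reward signals, one per rung of the pruning hierarchy:

* **devaluation progress** (full agent, C/B): the drop in the KL devaluation
  objective across one meta-model update, R = L_mm(psi_before) -
  L_mm(psi_after).  Positive when the catcher genuinely improved; this is the
  heterostatic drive.
* **learning progress** (C/PE): the same before-minus-after construction with
  the forward model's squared prediction error in place of the KL — the
  classic prediction-error curiosity baseline.
* **replayed rewards** (PG/IRS): rewards recorded from a full agent's run,
  re-sampled in temporal synchrony (a query at step t draws uniformly from
  the records labelled t).
* **surrogate Gaussian rewards** (PG/GR): time-invariant draws from
  N(0, 0.01^2) — the equilibrium-devaluation-progress null.

Rewards are plain floats in nats (or squared state units for learning
progress); nothing here participates in gradient bookkeeping.
"""

from __future__ import annotations

import numpy as np

from .belief import ForwardModel, MetaModel, devaluation_objective

__all__ = [
    "RewardDatabase",
    "devaluation_progress",
    "learning_progress",
    "replay_reward",
    "surrogate_reward",
    "SURROGATE_MEAN",
    "SURROGATE_SD",
]

SURROGATE_MEAN = 0.0
SURROGATE_SD = 0.01


def devaluation_progress(a, s, fm: ForwardModel, mm_before: MetaModel,
                         mm_after: MetaModel) -> float:
    """R = L_mm(psi_before) - L_mm(psi_after) on a fixed (a, s)."""
    return devaluation_objective(a, s, fm, mm_before) - devaluation_objective(
        a, s, fm, mm_after
    )


def learning_progress(s_next, a, s, fm_before: ForwardModel,
                      fm_after: ForwardModel) -> float:
    """R = ||s' - f(a,s; theta_before)||^2 - ||s' - f(a,s; theta_after)||^2."""
    return float(fm_before.mse_losses(s, a, s_next)[0] - fm_after.mse_losses(s, a, s_next)[0])


class RewardDatabase:
    """Time-indexed store of intrinsic reward samples from a full-agent run."""

    def __init__(self):
        self._records: dict[int, list[float]] = {}
        self._sorted_keys: np.ndarray | None = None

    def append(self, t: int, values) -> None:
        vals = np.atleast_1d(np.asarray(values, dtype=float))
        self._records.setdefault(int(t), []).extend(vals.tolist())
        self._sorted_keys = None

    def __len__(self) -> int:
        return sum(len(v) for v in self._records.values())

    @property
    def times(self) -> np.ndarray:
        if self._sorted_keys is None:
            self._sorted_keys = np.array(sorted(self._records), dtype=int)
        return self._sorted_keys

    def values_at(self, t: int) -> np.ndarray:
        return np.asarray(self._records[int(t)], dtype=float)

    def nearest_time(self, t: int) -> int:
        keys = self.times
        if len(keys) == 0:
            raise ValueError(
                "reward database is empty: run the full (C/B) agent first to "
                "populate it"
            )
        i = np.searchsorted(keys, t)
        if i == 0:
            return int(keys[0])
        if i == len(keys):
            return int(keys[-1])
        return int(keys[i - 1] if t - keys[i - 1] <= keys[i] - t else keys[i])

    # -- persistence -----------------------------------------------------
    def to_frame(self):
        import pandas as pd

        ts, vs = [], []
        for t in sorted(self._records):
            for v in self._records[t]:
                ts.append(t)
                vs.append(v)
        return pd.DataFrame({"t": ts, "value": vs})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RewardDatabase":
        import pandas as pd

        df = pd.read_csv(path)
        db = cls()
        for t, group in df.groupby("t"):
            db.append(int(t), group["value"].to_numpy())
        return db

    def to_npz(self, path) -> None:
        df = self.to_frame()
        np.savez(path, t=df["t"].to_numpy(), value=df["value"].to_numpy())

    @classmethod
    def from_npz(cls, path) -> "RewardDatabase":
        z = np.load(path)
        db = cls()
        for t in np.unique(z["t"]):
            db.append(int(t), z["value"][z["t"] == t])
        return db


def replay_reward(db: RewardDatabase, t: int, rng: np.random.Generator) -> float:
    """A recorded reward for time step ``t``, drawn uniformly among its records.

    Falls back to the nearest labelled time step when ``t`` itself carries no
    record, preserving temporal synchrony across runs of unequal length.
    """
    key = int(t) if int(t) in db._records else db.nearest_time(int(t))
    vals = db.values_at(key)
    return float(vals[rng.integers(len(vals))])


def surrogate_reward(rng: np.random.Generator, mean: float = SURROGATE_MEAN,
                     sd: float = SURROGATE_SD) -> float:
    """Time-invariant Gaussian surrogate reward ~ N(0, 0.01^2)."""
    return float(rng.normal(mean, sd))
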