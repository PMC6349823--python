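"""Oracle grid dataset, splits, supervised training and benchmarking.

The oracle dataset removes the agent from the loop: the state-action space
is divided into an even grid (full scale 49x49 positions x 11x11 velocities
x 11x11 actions, ~35M entries), every point is pushed once through the
physics, and the resulting (s, a, s') records form an unbiased supervised
set — including regions the force field makes essentially inaccessible to
any interactive agent.  A forward model trained on this set ("Oracle") upper-
bounds what self-collected experience could achieve, and its held-out
validation split is the common yardstick on which every agent variant is
scored.

Scores are reported as *error percentage*: 100 x RMSE / (maximum pairwise
Euclidean distance among the validation next-states), so they are
comparable across grid scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import env as envmod
from .belief import ForwardModel
from .nets import Adam

__all__ = [
    "OracleGridSpec",
    "TransitionDataset",
    "DatasetSplit",
    "generate_oracle_dataset",
    "split_dataset",
    "PlateauScheduler",
    "train_oracle",
    "error_percentage",
    "max_pairwise_distance",
]


@dataclass
class OracleGridSpec:
    """Even grid over positions, velocities and actions.

    ``n_pos``/``n_vel``/``n_act`` are per-axis counts; the full-scale
    configuration is (49, 49) x (11, 11) x (11, 11).  Velocity bounds default
    to [-2, 2] per axis, matching the acceleration scale.
    """

    n_pos: tuple[int, int] = (49, 49)
    n_vel: tuple[int, int] = (11, 11)
    n_act: tuple[int, int] = (11, 11)
    vel_range: tuple[float, float] = (-2.0, 2.0)

    @property
    def n_records(self) -> int:
        return int(np.prod(self.n_pos) * np.prod(self.n_vel) * np.prod(self.n_act))


@dataclass
class TransitionDataset:
    """Flat arrays of (s, a, s') records; ``a`` is the continuous (ax, ay)."""

    s: np.ndarray
    a: np.ndarray
    s_next: np.ndarray

    def __len__(self) -> int:
        return len(self.s)

    def subset(self, idx: np.ndarray) -> "TransitionDataset":
        return TransitionDataset(self.s[idx], self.a[idx], self.s_next[idx])

    def save_npz(self, path) -> None:
        np.savez(path, s=self.s, a=self.a, s_next=self.s_next)

    @classmethod
    def load_npz(cls, path) -> "TransitionDataset":
        z = np.load(path)
        return cls(z["s"], z["a"], z["s_next"])


@dataclass
class DatasetSplit:
    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray


def generate_oracle_dataset(spec: OracleGridSpec, config: envmod.EnvConfig,
                            max_records: int = 5_000_000) -> TransitionDataset:
    """One deterministic physics evaluation per grid point.

    ``max_records`` guards against accidentally materialising the 35M-record
    full grid in memory; generate shards over position slices for that scale.
    """
    if spec.n_records > max_records:
        raise ValueError(
            f"{spec.n_records} records exceed max_records={max_records}; "
            "generate in shards or reduce the grid"
        )
    px = np.linspace(0.0, 1.0, spec.n_pos[0])
    py = np.linspace(0.0, 1.0, spec.n_pos[1])
    vlo, vhi = spec.vel_range
    vx = np.linspace(vlo, vhi, spec.n_vel[0])
    vy = np.linspace(vlo, vhi, spec.n_vel[1])
    lo, hi = envmod.ACTION_RANGE
    ax = np.linspace(lo, hi, spec.n_act[0])
    ay = np.linspace(lo, hi, spec.n_act[1])

    grids = np.meshgrid(px, py, vx, vy, ax, ay, indexing="ij")
    cols = [g.ravel() for g in grids]
    s = np.column_stack(cols[:4])
    a = np.column_stack(cols[4:])
    s_next = np.empty_like(s)

    # the force field depends only on position: evaluate it once per (x, y)
    field = {}
    for xi in px:
        for yi in py:
            field[(xi, yi)] = envmod.field_force((xi, yi), config)
    forces = np.array([field[(row[0], row[1])] for row in s])

    total = a + forces
    if config.damping:
        total = total - config.damping * s[:, 2:]
    new_v = s[:, 2:] + config.dt * total
    new_p = s[:, :2] + config.dt * new_v
    s_next[:, :2] = new_p
    s_next[:, 2:] = new_v
    for axis in range(2):
        low = s_next[:, axis] < 0.0
        high = s_next[:, axis] > 1.0
        s_next[low, axis] = 0.0
        s_next[high, axis] = 1.0
        s_next[low | high, 2 + axis] = 0.0
    if config.zero_both_velocities:
        hit = (new_p < 0.0).any(axis=1) | (new_p > 1.0).any(axis=1)
        s_next[hit, 2:] = 0.0
    return TransitionDataset(s, a, s_next)


def split_dataset(n: int, ratios=(0.8, 0.16, 0.04), seed: int | None = None) -> DatasetSplit:
    """Disjoint train/test/validation index sets sampled without replacement."""
    if sum(ratios) > 1.0 + 1e-9:
        raise ValueError("split ratios must sum to at most 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(ratios[0] * n))
    n_test = int(round(ratios[1] * n))
    n_val = int(round(ratios[2] * n))
    return DatasetSplit(
        train=perm[:n_train],
        test=perm[n_train:n_train + n_test],
        validation=perm[n_train + n_test:n_train + n_test + n_val],
    )


class PlateauScheduler:
    """Reduce-on-plateau: lr <- factor * lr after ``patience`` stale epochs.

    Epochs are 0-indexed; the call at epoch 0 sets the baseline.  On a
    constant loss sequence the counter reaches ``patience`` at epoch
    ``patience`` exactly, so reductions fire at epochs 3000, 6000, ... with
    the default patience.
    """

    def __init__(self, optimizers, factor: float = 0.1, patience: int = 3000,
                 min_delta: float = 0.0):
        self.optimizers = list(optimizers) if isinstance(optimizers, (list, tuple)) else [optimizers]
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.stale = 0
        self.reductions: list[int] = []
        self.epoch = -1

    def step(self, metric: float) -> bool:
        """Register one epoch's monitored loss; returns True if lr was cut."""
        self.epoch += 1
        if metric < self.best - self.min_delta:
            self.best = metric
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            for opt in self.optimizers:
                opt.lr *= self.factor
            self.stale = 0
            self.reductions.append(self.epoch)
            return True
        return False


def train_oracle(dataset: TransitionDataset, split: DatasetSplit, fm: ForwardModel,
                 epochs: int = 60_000, batch_size: int = 128, lr: float = 1e-4,
                 seed: int | None = None, plateau_patience: int = 3000,
                 test_eval_size: int = 2048, eval_every: int = 50):
    """Supervised forward-model training on the oracle train split.

    One "epoch" is one optimizer step on one sampled batch.  The learning
    rate is scheduled on the test-split error (evaluated on a fixed
    subsample every ``eval_every`` epochs to keep the monitor cheap).
    Returns (fm, history dict).
    """
    rng = np.random.default_rng(seed)
    opt = Adam(fm.parameters(), lr=lr)
    sched = PlateauScheduler(opt, patience=plateau_patience)
    train_idx = split.train
    test_idx = split.test
    if len(test_idx) > test_eval_size:
        test_idx = rng.choice(test_idx, size=test_eval_size, replace=False)
    test_s, test_a, test_sn = dataset.s[test_idx], dataset.a[test_idx], dataset.s_next[test_idx]

    losses, test_losses = [], []
    test_loss = np.inf
    for epoch in range(epochs):
        take = min(batch_size, len(train_idx))
        bi = train_idx[rng.choice(len(train_idx), size=take, replace=False)]
        fm.zero_grad()
        loss = fm.mse_backward(dataset.s[bi], dataset.a[bi], dataset.s_next[bi])
        opt.step()
        losses.append(loss)
        if epoch % eval_every == 0 or epoch == epochs - 1:
            test_loss = float(np.mean(fm.mse_losses(test_s, test_a, test_sn)))
            test_losses.append((epoch, test_loss))
        sched.step(test_loss)
    return fm, {"train_loss": np.array(losses), "test_loss": test_losses,
                "lr_reductions": sched.reductions}


def max_pairwise_distance(points: np.ndarray, brute_limit: int = 4000) -> float:
    """Exact diameter of a point set.

    Brute force for small sets; otherwise the convex hull is computed first
    (the diameter is attained between hull vertices) and the O(m^2) scan runs
    on the vertices only.  Falls back to chunked brute force if the hull is
    degenerate.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty point set")
    if len(pts) > brute_limit:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate geometry: fall through to chunked brute force
    best = 0.0
    chunk = 2000
    for i in range(0, len(pts), chunk):
        block = pts[i:i + chunk]
        d2 = np.sum((block[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))


def error_percentage(fm: ForwardModel, dataset: TransitionDataset,
                     idx: np.ndarray | None = None, batch: int = 8192,
                     denominator: float | None = None) -> float:
    """100 * RMSE / max pairwise distance over the validation next-states."""
    if idx is None:
        idx = np.arange(len(dataset))
    if len(idx) == 0:
        raise ValueError("validation set is empty")
    sq = 0.0
    for i in range(0, len(idx), batch):
        bi = idx[i:i + batch]
        sq += float(np.sum(fm.mse_losses(dataset.s[bi], dataset.a[bi], dataset.s_next[bi])))
    rmse = np.sqrt(sq / len(idx))
    if denominator is None:
        denominator = max_pairwise_distance(dataset.s_next[idx])
    return 100.0 * rmse / denominator


def validation_mse(fm: ForwardModel, dataset: TransitionDataset,
                   idx: np.ndarray, batch: int = 8192) -> float:
    """Mean squared validation loss ||s' - f(a,s)||^2."""
    sq = 0.0
    for i in range(0, len(idx), batch):
        bi = idx[i:i + batch]
        sq += float(np.sum(fm.mse_losses(dataset.s[bi], dataset.a[bi], dataset.s_next[bi])))
    return sq / len(idx)
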