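"""Deterministic 2D attractor/repeller world — a planar Mountain-Car relative.

The agent lives on the unit square with state (x, y, vx, vy).  It chooses a
discrete acceleration from an 11x11 grid on [-2, 2]^2; point attractors pull
and point repellers push with a radially symmetric, Gaussian-decaying force
that is added to the chosen acceleration.  There is no external reward and no
terminal state: the world exists purely so the agent can gather transitions.

Physics is explicit Euler (velocity before position).  On crossing a wall the
violated axis is clamped and that axis's velocity zeroed while the other axis
is untouched, so the agent can slide along walls and can be trapped in
corners.  Every operation is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "FieldSource",
    "EnvConfig",
    "EnvState",
    "ActionGrid",
    "field_force",
    "step",
    "step_accel",
    "reset",
    "rollout",
]

N_ACTION_LEVELS = 11
ACTION_RANGE = (-2.0, 2.0)
N_ACTIONS = N_ACTION_LEVELS**2


@dataclass(frozen=True)
class FieldSource:
    """A point source: attractors pull toward it, repellers push away."""

    position: tuple[float, float]
    strength: float


@dataclass
class EnvConfig:
    """Environment layout and physics constants.

    ``sigma`` is the decay scale of each source's Gaussian force profile
    ``strength * exp(-r^2 / (2 sigma^2))``.  ``zero_both_velocities`` switches
    the boundary rule from per-axis zeroing (sliding allowed, the default) to
    zeroing both components on any wall contact.
    """

    attractors: list[FieldSource] = field(
        default_factory=lambda: [FieldSource((0.75, 0.75), 1.8)]
    )
    repellers: list[FieldSource] = field(
        default_factory=lambda: [
            FieldSource((0.25, 0.75), 1.5),
            FieldSource((0.75, 0.25), 1.5),
            FieldSource((0.25, 0.25), 1.5),
        ]
    )
    sigma: float = 0.25
    force_scale: float = 1.0
    dt: float = 0.05
    damping: float = 0.5
    initial_position: tuple[float, float] = (0.5, 0.5)
    zero_both_velocities: bool = False

    def __post_init__(self):
        self.attractors = [
            s if isinstance(s, FieldSource) else FieldSource(tuple(s[0]), float(s[1]))
            for s in self.attractors
        ]
        self.repellers = [
            s if isinstance(s, FieldSource) else FieldSource(tuple(s[0]), float(s[1]))
            for s in self.repellers
        ]
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        for s in self.attractors + self.repellers:
            if not np.isfinite(s.strength) or not np.all(np.isfinite(s.position)):
                raise ValueError("source positions and strengths must be finite")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["attractors"] = [[list(s.position), s.strength] for s in self.attractors]
        d["repellers"] = [[list(s.position), s.strength] for s in self.repellers]
        d["initial_position"] = list(self.initial_position)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnvConfig":
        d = dict(d)
        if "attractors" in d:
            d["attractors"] = [FieldSource(tuple(p), float(s)) for p, s in d["attractors"]]
        if "repellers" in d:
            d["repellers"] = [FieldSource(tuple(p), float(s)) for p, s in d["repellers"]]
        if "initial_position" in d:
            d["initial_position"] = tuple(d["initial_position"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "EnvConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# An EnvState is a plain length-4 float array (x, y, vx, vy); positions live
# in [0,1]^2, velocities are unbounded.
EnvState = np.ndarray


def make_state(x: float, y: float, vx: float = 0.0, vy: float = 0.0) -> EnvState:
    return np.array([x, y, vx, vy], dtype=float)


class ActionGrid:
    """The 11x11 discrete acceleration grid on [-2, 2]^2.

    Index ``i`` in [0, 120] maps to (ax, ay) = (levels[i // 11], levels[i % 11]).
    """

    def __init__(self):
        self.levels = np.linspace(ACTION_RANGE[0], ACTION_RANGE[1], N_ACTION_LEVELS)
        ix, iy = np.divmod(np.arange(N_ACTIONS), N_ACTION_LEVELS)
        self.accelerations = np.column_stack([self.levels[ix], self.levels[iy]])

    def __len__(self) -> int:
        return N_ACTIONS

    def acceleration(self, index: int) -> np.ndarray:
        if not 0 <= index < N_ACTIONS:
            raise ValueError(f"action index {index} outside [0, {N_ACTIONS - 1}]")
        return self.accelerations[index]


ACTIONS = ActionGrid()


def field_force(position, config: EnvConfig) -> np.ndarray:
    """Net acceleration exerted by all attractors and repellers at ``position``.

    Each source contributes ``strength * exp(-r^2 / (2 sigma^2))`` along the
    unit vector toward (attractor) or away from (repeller) the source; the
    magnitude is bounded at r=0 and decays smoothly with distance.
    """
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("non-finite position: corrupted state")
    total = np.zeros(2)
    two_sig2 = 2.0 * config.sigma**2
    for sign, sources in ((1.0, config.attractors), (-1.0, config.repellers)):
        for src in sources:
            d = np.asarray(src.position) - position
            r = np.hypot(d[0], d[1])
            if r < 1e-12:
                continue  # force direction undefined at the source centre
            mag = src.strength * np.exp(-(r**2) / two_sig2)
            total += sign * mag * d / r
    return config.force_scale * total


def step_accel(state: EnvState, accel, config: EnvConfig) -> EnvState:
    """Advance one time step under a continuous acceleration command."""
    state = np.asarray(state, dtype=float)
    accel = np.asarray(accel, dtype=float)
    pos, vel = state[:2], state[2:]
    total = accel + field_force(pos, config)
    if config.damping:
        total = total - config.damping * vel
    new_vel = vel + config.dt * total
    new_pos = pos + config.dt * new_vel
    new_vel = new_vel.copy()
    hit = False
    for ax in range(2):
        if new_pos[ax] < 0.0:
            new_pos[ax] = 0.0
            new_vel[ax] = 0.0
            hit = True
        elif new_pos[ax] > 1.0:
            new_pos[ax] = 1.0
            new_vel[ax] = 0.0
            hit = True
    if hit and config.zero_both_velocities:
        new_vel[:] = 0.0
    return np.concatenate([new_pos, new_vel])


def step(state: EnvState, action_index: int, config: EnvConfig) -> EnvState:
    """Advance one time step under discrete action ``action_index``."""
    return step_accel(state, ACTIONS.acceleration(int(action_index)), config)


def reset(config: EnvConfig) -> EnvState:
    """Initial state: the configured start marker with zero velocities."""
    x, y = config.initial_position
    return make_state(x, y, 0.0, 0.0)


def rollout(config: EnvConfig, steps: int, policy: str = "random",
            seed: int | None = None, action_sequence=None):
    """Roll the environment forward and return a trajectory record.

    Returns dict of arrays: t, state (steps+1, 4), action (steps,).
    ``policy='random'`` draws uniform actions; alternatively pass an explicit
    ``action_sequence``.
    """
    rng = np.random.default_rng(seed)
    if action_sequence is not None:
        actions = np.asarray(action_sequence, dtype=int)
        steps = len(actions)
    elif policy == "random":
        actions = rng.integers(0, N_ACTIONS, size=steps)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    states = np.empty((steps + 1, 4))
    states[0] = reset(config)
    for t in range(steps):
        states[t + 1] = step(states[t], actions[t], config)
    return {"t": np.arange(steps + 1), "state": states, "action": actions}


def save_trajectory_npz(traj: dict, path) -> None:
    """Binary trajectory container: t, state (T+1, 4), action (T,)."""
    np.savez(path, t=traj["t"], state=traj["state"], action=traj["action"])


def load_trajectory_npz(path) -> dict:
    z = np.load(path)
    return {"t": z["t"], "state": z["state"], "action": z["action"]}


def trajectory_frame(traj: dict):
    """Per-step trajectory records as a pandas DataFrame (t, x, y, vx, vy, action)."""
    import pandas as pd

    states = traj["state"][:-1]
    return pd.DataFrame(
        {
            "t": traj["t"][:-1],
            "x": states[:, 0],
            "y": states[:, 1],
            "vx": states[:, 2],
            "vy": states[:, 3],
            "action_index": traj["action"],
        }
    )
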