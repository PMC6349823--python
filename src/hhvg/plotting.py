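"""Utilitarian plots: force field, trajectories, coverage curves."""

from __future__ import annotations

import numpy as np

from .env import EnvConfig, field_force


def plot_force_field(config: EnvConfig | None = None, n: int = 20, ax=None):
    """Quiver plot of the attractor/repeller field on the unit square."""
    import matplotlib.pyplot as plt

    config = config or EnvConfig()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xs = np.linspace(0.02, 0.98, n)
    ys = np.linspace(0.02, 0.98, n)
    U = np.empty((n, n))
    V = np.empty((n, n))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            f = field_force((x, y), config)
            U[j, i], V[j, i] = f
    ax.quiver(xs, ys, U, V, angles="xy")
    for src in config.attractors:
        ax.plot(*src.position, "rx", markersize=10)
    for src in config.repellers:
        ax.plot(*src.position, "k^", markersize=8)
    ax.plot(*config.initial_position, "b*", markersize=12)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_aspect("equal")
    return ax


def plot_trajectory(states: np.ndarray, config: EnvConfig | None = None, ax=None):
    """Positional trace of a rollout over the force field."""
    ax = plot_force_field(config, ax=ax)
    ax.plot(states[:, 0], states[:, 1], "-", lw=0.5, alpha=0.7, color="tab:blue")
    return ax


def plot_coverage(series_by_variant: dict, which: str = "coverage_rate", ax=None):
    """Coverage-rate or coverage-entropy curves, one line per variant."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, series in series_by_variant.items():
        ax.plot(series, label=name)
    ax.set_xlabel("environment step")
    ax.set_ylabel(which.replace("_", " "))
    ax.legend()
    return ax
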