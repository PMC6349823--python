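"""Oracle grid dataset, splits, scheduler contract, benchmarking."""

import numpy as np
import pytest

from hhvg.belief import ForwardModel
from hhvg.env import EnvConfig, step_accel
from hhvg.nets import Adam
from hhvg.oracle import (
    OracleGridSpec,
    PlateauScheduler,
    error_percentage,
    generate_oracle_dataset,
    max_pairwise_distance,
    split_dataset,
    train_oracle,
    validation_mse,
)


class TestGridGeneration:
    def test_full_scale_record_count_arithmetic(self):
        spec = OracleGridSpec()
        assert spec.n_records == 49 * 49 * 11 * 11 * 11 * 11 == 35_153_041

    def test_reduced_grid_count(self, env_config):
        spec = OracleGridSpec(n_pos=(3, 3), n_vel=(3, 3), n_act=(3, 3))
        ds = generate_oracle_dataset(spec, env_config)
        assert len(ds) == 729

    def test_every_record_satisfies_the_physics(self, env_config):
        spec = OracleGridSpec(n_pos=(3, 3), n_vel=(3, 3), n_act=(3, 3))
        ds = generate_oracle_dataset(spec, env_config)
        for i in range(0, len(ds), 37):
            expected = step_accel(ds.s[i], ds.a[i], env_config)
            assert np.allclose(ds.s_next[i], expected, atol=1e-12)

    def test_oversized_grid_guarded(self, env_config):
        with pytest.raises(ValueError, match="shards"):
            generate_oracle_dataset(OracleGridSpec(), env_config)

    def test_covers_repeller_adjacent_cells_beyond_agent_buffer(self, env_config):
        """The grid includes repeller-adjacent positions that a random-walk
        buffer does not reach."""
        from hhvg.env import rollout
        from hhvg.metrics import _cells

        spec = OracleGridSpec(n_pos=(25, 25), n_vel=(2, 2), n_act=(2, 2))
        ds = generate_oracle_dataset(spec, env_config)
        oracle_cells = set(_cells(ds.s[:, :2]).tolist())
        traj = rollout(env_config, steps=2000, seed=0)
        agent_cells = set(_cells(traj["state"][:-1, :2]).tolist())
        rep = np.array(env_config.repellers[0].position)
        near_rep = {
            c for c in oracle_cells
            if np.linalg.norm([(c // 50 + 0.5) / 50 - rep[0],
                               (c % 50 + 0.5) / 50 - rep[1]]) < 0.1
        }
        assert len(near_rep - agent_cells) > 0
        assert len(oracle_cells) > len(agent_cells)


class TestSplits:
    def test_split_sizes(self):
        split = split_dataset(1000, seed=0)
        assert len(split.train) == 800
        assert len(split.test) == 160
        assert len(split.validation) == 40

    def test_disjoint_union(self):
        split = split_dataset(500, seed=1)
        all_idx = np.concatenate([split.train, split.test, split.validation])
        assert len(np.unique(all_idx)) == len(all_idx)

    def test_seed_reproducible(self):
        a = split_dataset(300, seed=9)
        b = split_dataset(300, seed=9)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.validation, b.validation)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(100, ratios=(0.8, 0.3, 0.1))


class TestPlateauScheduler:
    def test_constant_loss_fires_at_patience_multiples(self):
        opt = Adam([], lr=1.0)
        sched = PlateauScheduler(opt, patience=3000)
        for _ in range(7000):
            sched.step(1.0)
        assert sched.reductions[:2] == [3000, 6000]
        assert np.isclose(opt.lr, 0.01)

    def test_improving_loss_never_reduces(self):
        opt = Adam([], lr=1.0)
        sched = PlateauScheduler(opt, patience=10)
        for i in range(100):
            sched.step(100.0 - i)
        assert sched.reductions == []
        assert opt.lr == 1.0

    def test_counter_resets_after_improvement(self):
        opt = Adam([], lr=1.0)
        sched = PlateauScheduler(opt, patience=5)
        for _ in range(4):
            sched.step(1.0)
        sched.step(0.5)  # improvement resets the stale counter
        for _ in range(4):
            sched.step(0.5)
        assert sched.reductions == []


class TestOracleTraining:
    def test_zero_epochs_returns_model_unchanged(self, env_config, rng):
        spec = OracleGridSpec(n_pos=(3, 3), n_vel=(2, 2), n_act=(2, 2))
        ds = generate_oracle_dataset(spec, env_config)
        split = split_dataset(len(ds), seed=0)
        fm = ForwardModel(rng, width=8)
        before = fm.state_dict()
        fm, hist = train_oracle(ds, split, fm, epochs=0, seed=0)
        after = fm.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_training_beats_untrained_baseline(self, env_config):
        spec = OracleGridSpec(n_pos=(4, 4), n_vel=(3, 3), n_act=(3, 3))
        ds = generate_oracle_dataset(spec, env_config)
        split = split_dataset(len(ds), seed=2)
        fm = ForwardModel(np.random.default_rng(2), width=32)
        untrained = validation_mse(fm, ds, split.validation)
        fm, _ = train_oracle(ds, split, fm, epochs=1500, lr=1e-3, seed=2)
        trained = validation_mse(fm, ds, split.validation)
        assert trained < untrained / 10


class TestErrorPercentage:
    def test_perfect_model_zero_percent(self, env_config, rng):
        """A model reproducing the empty-field linear physics exactly."""
        cfg = EnvConfig(attractors=[], repellers=[], damping=0.0)
        spec = OracleGridSpec(n_pos=(3, 3), n_vel=(3, 3), n_act=(3, 3))
        ds = generate_oracle_dataset(spec, cfg)
        fm = ForwardModel(rng, width=8)
        # force the exact linear dynamics: s' = A0 s + C0 a
        dt = cfg.dt
        A0 = np.array([[1, 0, dt, 0], [0, 1, 0, dt], [0, 0, 1, 0], [0, 0, 0, 1.0]])
        A0[:2, 2:] = dt * np.eye(2) * 1.0
        A0[0, 2] = A0[1, 3] = dt
        C0 = np.array([[dt * dt, 0], [0, dt * dt], [dt, 0], [0, dt]])
        for head, val in ((fm.head_A, A0.ravel()), (fm.head_B, np.zeros(32)),
                          (fm.head_C, C0.ravel()), (fm.head_o, np.zeros(4))):
            head.W[...] = 0.0
            head.b[...] = val
        interior = ~(
            (ds.s_next[:, 0] <= 0) | (ds.s_next[:, 0] >= 1)
            | (ds.s_next[:, 1] <= 0) | (ds.s_next[:, 1] >= 1)
        )
        idx = np.flatnonzero(interior)
        assert error_percentage(fm, ds, idx) < 1e-10

    def test_direct_ratio(self, rng):
        from hhvg.oracle import TransitionDataset

        fm = ForwardModel(rng, width=8)
        s = np.zeros((2, 4))
        a = np.zeros((2, 2))
        s_next = np.array([[0.0, 0, 0, 0], [2.0, 0, 0, 0]])  # distance 2 apart
        pred = fm.mean(s, a)
        rmse = np.sqrt(np.mean(np.sum((pred - s_next) ** 2, axis=1)))
        ds = TransitionDataset(s, a, s_next)
        assert np.isclose(error_percentage(fm, ds), 100 * rmse / 2.0)

    def test_diameter_matches_brute_force(self, rng):
        pts = rng.normal(size=(100, 4))
        brute = max(
            np.linalg.norm(pts[i] - pts[j])
            for i in range(100) for j in range(i + 1, 100)
        )
        assert np.isclose(max_pairwise_distance(pts), brute)

    def test_diameter_hull_path_matches_brute_force(self, rng):
        pts = rng.normal(size=(5000, 4))
        exact = max_pairwise_distance(pts, brute_limit=10_000)  # pure brute
        hull = max_pairwise_distance(pts, brute_limit=1000)  # hull shortcut
        assert np.isclose(hull, exact)

    def test_empty_validation_rejected(self, env_config, rng):
        spec = OracleGridSpec(n_pos=(2, 2), n_vel=(2, 2), n_act=(2, 2))
        ds = generate_oracle_dataset(spec, env_config)
        fm = ForwardModel(rng, width=8)
        with pytest.raises(ValueError):
            error_percentage(fm, ds, np.array([], dtype=int))
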