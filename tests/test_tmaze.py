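"""Maze embedding, rat drive, cue wiring and trial scheduling."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import mazesweep as mz
from mazesweep.config import ConfigurationError
from mazesweep.tmaze import cue_window, trip_duration


@pytest.fixture(scope="module")
def full_maze(default_geometry):
    return mz.build_maze(default_geometry, mz.MazeSpec())


class TestMazeMasks:
    def test_corridor_width_is_11(self, full_maze):
        n = full_maze.grid_size
        lab = full_maze.maze.reshape(n, n)
        _, y_A = full_maze.decision_point
        cx, y_D = full_maze.start
        # stem cross-section halfway up the stem
        row = lab[:, (y_D + y_A) // 2]
        assert row.sum() == 11
        # arm cross-section at the right goal zone
        col = lab[cx + 5 + 35, :]
        assert col.sum() == 11

    def test_membership_counts_match_hand_enumeration(self, tiny_geometry):
        """Toy maze (stem 8, arms 5, width 3): counts from closed-form
        corridor areas."""
        spec = mz.MazeSpec(width=3, stem_len=8, arm_len=5,
                           goal_zone_len=2, cue_zone_len=3)
        masks = mz.build_maze(tiny_geometry, spec)
        # top corridor: width 3 rows x (2*5 + 3) columns
        assert masks.left_arm.sum() == 3 * 5
        assert masks.right_arm.sum() == 3 * 5
        assert masks.goal_left.sum() == 3 * 2
        assert masks.goal_right.sum() == 3 * 2
        assert masks.cue_zone.sum() == 3 * 3
        # stem columns: 3 wide, from y_D up to the corridor's top edge
        assert masks.stem.sum() == 3 * (8 + 2)
        # union: corridor (13x3) + stem (3x10) minus the 3x3 junction overlap
        assert masks.maze.sum() == 13 * 3 + 3 * (8 + 2) - 9

    def test_zones_are_disjoint(self, full_maze):
        assert not np.any(full_maze.goal_left & full_maze.goal_right)
        assert not np.any(full_maze.left_arm & full_maze.right_arm)
        assert not np.any(full_maze.stem & (full_maze.left_arm | full_maze.right_arm))

    def test_oversized_maze_rejected(self, tiny_geometry):
        with pytest.raises(ConfigurationError):
            mz.build_maze(tiny_geometry, mz.MazeSpec())

    def test_label_grid_roundtrip(self, full_maze):
        lab = full_maze.label_grid()
        assert (lab > 0).sum() == full_maze.maze.sum()


class TestRatDrive:
    def test_trip_and_gap_timing(self, full_maze):
        task = mz.TaskConfig()
        assert trip_duration(full_maze, task) == pytest.approx(105.0)
        assert task.trial_gap == 150.0

    def test_drive_zero_beyond_place_field(self, full_maze):
        task = mz.TaskConfig()
        pos, drive, _ = mz.rat_drive(full_maze, "train", "R", 10.0, task)
        n = full_maze.grid_size
        xs, ys = np.divmod(np.arange(n * n), n)
        d = np.hypot(xs - pos[0], ys - pos[1])
        assert np.all(drive[d > task.place_field_radius] == 0.0)
        assert drive[full_maze.maze & (d < 3)].min() > 0.0

    def test_blocked_arm_clamped_whole_trial(self, full_maze):
        task = mz.TaskConfig()
        for t in (0.0, 50.0, 100.0):
            _, drive, clamp = mz.rat_drive(full_maze, "train", "R", t, task)
            assert np.all(clamp[full_maze.left_arm])
            assert np.all(drive[full_maze.left_arm] == 0.0)
        # cue C2 -> goal right -> left arm blocked; mirror for C1
        _, _, clamp_l = mz.rat_drive(full_maze, "train", "L", 10.0, task)
        assert np.all(clamp_l[full_maze.right_arm])
        assert not np.all(clamp_l[full_maze.left_arm])

    def test_test_trial_halts_at_decision_point(self, full_maze):
        task = mz.TaskConfig()
        pos_late = mz.rat_position(full_maze, "test", None, 500.0, task)
        assert pos_late == tuple(map(float, full_maze.decision_point))

    def test_training_rat_reaches_arm_end(self, full_maze):
        task = mz.TaskConfig()
        pos = mz.rat_position(full_maze, "train", "L", 1000.0, task)
        cx, _ = full_maze.decision_point
        assert pos[0] == cx - 5 - full_maze.spec.arm_len


class TestCueWiring:
    def test_exactly_n_synapses_per_cue(self, default_geometry):
        task = mz.TaskConfig()
        cues = mz.wire_cues(default_geometry, task, np.random.default_rng(0))
        assert cues.targets.shape == (2, 40_000)
        assert cues.n_synapses == 40_000
        assert cues.targets.min() >= 0
        assert cues.targets.max() < default_geometry.n_neurons

    def test_initial_weights_match_in_grid_distribution(self, default_geometry):
        """KS distance between the cue weight sample and the efferent
        weight population of an excitatory grid neuron is tiny."""
        task = mz.TaskConfig()
        cues = mz.wire_cues(default_geometry, task, np.random.default_rng(1))
        population = default_geometry.w_pre_E
        rng = np.random.default_rng(2)
        reference = rng.choice(population, size=40_000)
        stat, _ = ks_2samp(cues.w0[0], reference)
        assert stat < 0.01

    def test_cue_spike_times_regular(self):
        task = mz.TaskConfig(cue_rate=200.0)
        times = mz.cue_spike_times(40.0, 110.0, task)
        assert np.allclose(np.diff(times), 5.0)
        assert times[0] == 40.0 and times[-1] < 110.0

    def test_cue_window_tracks_rat_position(self, full_maze):
        """The cue plays while the rat is near A: it ends shortly after
        the junction on training trials but lasts through the hold on
        test trials (when the rat is parked at the decision point)."""
        task = mz.TaskConfig()
        t_A = full_maze.spec.stem_len / task.rat_speed
        t_on, t_off = cue_window(full_maze, task, "train")
        assert t_on == pytest.approx(t_A - full_maze.spec.cue_zone_len)
        assert t_off == pytest.approx(t_A + task.cue_post_ms)
        t_on2, t_off2 = cue_window(full_maze, task, "test")
        assert t_on2 == t_on
        assert t_off2 == pytest.approx(t_A + task.test_hold_ms)


class TestSchedule:
    def test_alternating_cues_and_balance(self):
        plan = mz.schedule_trials(10, np.ones(10), np.random.default_rng(0))
        train = [p for p in plan if p.kind == "train"]
        assert [p.cue for p in train] == ["C1", "C2"] * 5
        assert sum(p.cue == "C1" for p in train) == 5
        # g = 1: every goal is cue-congruent -> L and R goals balanced
        assert sum(p.goal_arm == "L" for p in train) == 5

    def test_every_training_trial_followed_by_test(self):
        plan = mz.schedule_trials(7, np.ones(7), np.random.default_rng(0))
        kinds = [p.kind for p in plan]
        assert kinds == ["train", "test"] * 7
        assert all(not p.plasticity for p in plan if p.kind == "test")
        assert all(p.plasticity for p in plan if p.kind == "train")
        assert all(p.blocked_arm is None for p in plan if p.kind == "test")

    def test_deterministic_congruent_goals(self):
        plan = mz.schedule_trials(6, np.ones(6), np.random.default_rng(0))
        train = [p for p in plan if p.kind == "train"]
        for p in train:
            assert p.congruent == 1
            assert p.goal_arm == ("L" if p.cue == "C1" else "R")
            assert p.blocked_arm != p.goal_arm

    def test_congruent_fraction_tracks_g(self):
        g = np.full(10_000, 0.5)
        plan = mz.schedule_trials(10_000, g, np.random.default_rng(42))
        frac = np.mean([p.congruent for p in plan if p.kind == "train"])
        assert frac == pytest.approx(0.5, abs=0.01)


class TestGSequences:
    def test_step_switch_values(self):
        g = mz.generate_g_sequence("step_switch", 200, n_switch=100)
        assert g[99] == 0.0 and g[100] == 1.0
        assert np.all(g[:100] == 0.0) and np.all(g[100:] == 1.0)

    def test_zero_variance_walk_is_constant(self):
        g = mz.generate_g_sequence("gaussian_walk", 50, rng=0, Q=0.0)
        assert np.all(g == 0.5)

    def test_walk_increment_variance(self):
        """Without clipping, Var(g_100 - g_0) = 100 Q."""
        Q = 1e-6   # small enough that the [0,1] clip never engages
        rng = np.random.default_rng(7)
        finals = [mz.generate_g_sequence("gaussian_walk", 101, rng=rng, Q=Q)[-1] - 0.5
                  for _ in range(10_000)]
        assert np.var(finals) == pytest.approx(100 * Q, rel=0.1)

    def test_walk_stays_in_unit_interval(self):
        g = mz.generate_g_sequence("gaussian_walk", 2000, rng=3, Q=0.01)
        assert g.min() >= 0.0 and g.max() <= 1.0

    def test_negative_variance_rejected(self):
        with pytest.raises(ConfigurationError):
            mz.generate_g_sequence("gaussian_walk", 10, rng=0, Q=-1.0)
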