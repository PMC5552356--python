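"""Outcome classification, learning curves, weight-structure measures."""

import numpy as np
import pandas as pd
import pytest

import mazesweep as mz
from mazesweep.records import SpikeRecord
from mazesweep.sequences import OutcomeRecord, bias_from_coo


@pytest.fixture(scope="module")
def maze(tiny_geometry):
    spec = mz.MazeSpec(width=3, stem_len=8, arm_len=5, goal_zone_len=2, cue_zone_len=3)
    return mz.build_maze(tiny_geometry, spec)


def _record(maze, neurons, times, duration=120.0):
    return SpikeRecord(neuron=np.asarray(neurons, dtype=np.int64),
                       t=np.asarray(times, dtype=float),
                       grid_size=maze.grid_size, duration=duration, trial_index=1,
                       kind="test", cue="C2")


def _zone_neurons(maze, arm, k):
    return np.flatnonzero(maze.goal_mask(arm))[:k]


class TestClassification:
    def test_spikes_only_in_associated_zone_is_correct(self, maze):
        neurons = _zone_neurons(maze, "R", 6)
        rec = _record(maze, neurons, np.linspace(30, 60, 6))
        out = mz.classify_outcome(rec, maze, "C2", cue_onset=20.0, window=80.0)
        assert out.outcome == "correct"
        assert out.n_spikes_assoc == 6 and out.n_spikes_other == 0
        assert out.first_spike_assoc == pytest.approx(30.0)

    def test_mirror_case_is_wrong_arm(self, maze):
        neurons = _zone_neurons(maze, "L", 6)
        rec = _record(maze, neurons, np.linspace(30, 60, 6))
        out = mz.classify_outcome(rec, maze, "C2", 20.0, 80.0)
        assert out.outcome == "wrong_arm"

    def test_both_zones_above_threshold_is_split(self, maze):
        neurons = np.concatenate([_zone_neurons(maze, "R", 5), _zone_neurons(maze, "L", 5)])
        rec = _record(maze, neurons, np.full(10, 50.0))
        out = mz.classify_outcome(rec, maze, "C2", 20.0, 80.0)
        assert out.outcome == "split"

    def test_no_goal_zone_spikes_is_none(self, maze):
        stem = np.flatnonzero(maze.stem)[:20]
        rec = _record(maze, stem, np.linspace(25, 90, 20))
        out = mz.classify_outcome(rec, maze, "C2", 20.0, 80.0)
        assert out.outcome == "none"

    def test_spikes_before_cue_onset_ignored(self, maze):
        neurons = _zone_neurons(maze, "R", 6)
        rec = _record(maze, neurons, np.full(6, 10.0))  # before onset
        out = mz.classify_outcome(rec, maze, "C2", 20.0, 80.0)
        assert out.outcome == "none"

    def test_window_outside_trial_rejected(self, maze):
        rec = _record(maze, [], [], duration=100.0)
        with pytest.raises(ValueError):
            mz.classify_outcome(rec, maze, "C2", 50.0, 80.0)

    def test_classes_exhaustive_and_exclusive(self, maze):
        rng = np.random.default_rng(0)
        for _ in range(30):
            k_r = int(rng.integers(0, 10))
            k_l = int(rng.integers(0, 10))
            neurons = np.concatenate([_zone_neurons(maze, "R", k_r),
                                      _zone_neurons(maze, "L", k_l)])
            rec = _record(maze, neurons, np.full(len(neurons), 40.0))
            out = mz.classify_outcome(rec, maze, "C2", 20.0, 80.0)
            assert out.outcome in ("correct", "wrong_arm", "split", "none")


class TestLearningCurve:
    def test_all_correct_gives_rate_one_sem_zero(self):
        outs = [[True, True], [True, True], [True, True], [True, True]]
        curve = mz.correct_rate_curve(outs)
        assert np.all(curve["rate"] == 1.0)
        assert np.all(curve["sem"] == 0.0)

    def test_three_of_five_hand_computation(self):
        col = [True, True, True, False, False]
        outs = [[v] for v in col]
        curve = mz.correct_rate_curve(outs)
        assert curve["rate"][0] == pytest.approx(0.6)
        sd = np.std([1, 1, 1, 0, 0], ddof=1)
        assert curve["sem"][0] == pytest.approx(sd / np.sqrt(5))

    def test_accepts_outcome_records(self):
        rec = OutcomeRecord(1, "correct", 6, 0, 30.0, None)
        wrong = OutcomeRecord(1, "wrong_arm", 0, 6, None, 30.0)
        curve = mz.correct_rate_curve([[rec], [wrong]])
        assert curve["rate"][0] == pytest.approx(0.5)

    def test_ragged_realizations_rejected(self):
        with pytest.raises(ValueError):
            mz.correct_rate_curve([[True, True], [True]])


def bias_scale(geo):
    """Magnitude scale of the uncancelled bias sum: sum_k |dx_k| w_k."""
    return float(np.abs(geo.off_dx) @ geo.w_pre_E)


class TestBiasMeasure:
    def test_isotropic_static_weights_cancel(self, default_geometry):
        bias = mz.bias_measure(default_geometry)
        assert np.abs(bias).max() < 1e-13 * bias_scale(default_geometry)

    def test_single_extra_connection_direct_evaluation(self, tiny_geometry):
        """One extra efferent synapse of weight w at x-offset -5 gives
        bias 5w for the source neuron."""
        geo = tiny_geometry
        n = geo.n
        src = geo.flat_index(10, 10)
        tgt = geo.flat_index(5, 10)   # x-offset -5
        w = 3e-7
        bias = bias_from_coo([tgt], [src], [w], geo)
        assert bias[src] == pytest.approx(5 * w)
        assert np.count_nonzero(bias) == 1

    def test_engine_dw_route_matches_coo_route(self, tiny_geometry):
        """Bias from the stencil dw array equals the explicit-synapse
        computation on random plastic weights."""
        geo = tiny_geometry
        rng = np.random.default_rng(5)
        maze_neurons = rng.choice(geo.n_neurons, size=25, replace=False)
        dw = rng.normal(0, 1e-8, size=(25, geo.n_offsets))
        bias = mz.bias_measure(geo, dw, maze_neurons)

        n = geo.n
        post_list, pre_list, w_list = [], [], []
        for row, src in enumerate(maze_neurons):
            sx, sy = divmod(int(src), n)
            for k in range(geo.n_offsets):
                tx = (sx + geo.off_dx[k]) % n
                ty = (sy + geo.off_dy[k]) % n
                post_list.append(tx * n + ty)
                pre_list.append(src)
                w_list.append(dw[row, k])
        expected = bias_from_coo(post_list, pre_list, w_list, geo)
        assert bias[maze_neurons] == pytest.approx(expected[maze_neurons], rel=1e-9)


class TestCueAsymmetryProfile:
    def test_untrained_profile_is_flat_zero(self, tiny_geometry, maze):
        task = mz.TaskConfig(n_cue_synapses=2000, place_field_radius=3.0)
        cues = mz.wire_cues(tiny_geometry, task, np.random.default_rng(0))
        prof = mz.cue_asymmetry_profile(cues, maze, "C2")
        filled = prof.dropna(subset=["mean_dw"])
        assert len(filled) > 0
        assert np.all(filled["mean_dw"] == 0.0)

    def test_profile_reports_sided_changes(self, tiny_geometry, maze):
        task = mz.TaskConfig(n_cue_synapses=2000, place_field_radius=3.0)
        cues = mz.wire_cues(tiny_geometry, task, np.random.default_rng(0))
        right = maze.right_arm[cues.targets[1]]
        cues.dw[1, right] = 1e-8
        prof = mz.cue_asymmetry_profile(cues, maze, "C2").set_index("column")
        assert prof.loc[4, "mean_dw"] == pytest.approx(1e-8)
        assert prof.loc[-4, "mean_dw"] == 0.0


class TestDeltaWSteadyState:
    A, dt5, tau, r = 1.2e-9, 5.0, 20.0, 0.9649

    def test_zero_association_gives_zero(self):
        g_bar, dw = mz.delta_w_ss_tracker(np.zeros(20), self.A, self.dt5, self.tau, self.r)
        assert np.all(dw == 0.0)

    def test_recursion_converges_to_closed_form(self):
        """Iterating the per-trial recursion at constant g reaches the
        fixed point F*g within 0.1% after ~7/(1-r) trials (geometric
        deficit r^n)."""
        g = np.full(300, 0.7)
        series = mz.delta_w_recursion(g, self.A, self.dt5, self.tau, self.r)
        F = self.A * np.exp(-self.dt5 / self.tau) / (1 - self.r)
        # geometric convergence: deficit r^n, so ~7/(1-r) trials reach 0.1%
        n_conv = int(np.ceil(7 / (1 - self.r)))
        assert series[n_conv] == pytest.approx(F * 0.7, rel=1e-3)
        assert series[-1] == pytest.approx(F * 0.7, rel=1e-5)

    def test_tracker_proportional_to_trailing_mean(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(0, 1, 400)
        g_bar, dw = mz.delta_w_ss_tracker(g, self.A, self.dt5, self.tau, self.r, N=50)
        F = self.A * np.exp(-self.dt5 / self.tau) / (1 - self.r)
        assert dw == pytest.approx(F * g_bar)
        assert g_bar[100] == pytest.approx(g[50:100].mean())

    def test_divergent_decay_rejected(self):
        with pytest.raises(ValueError):
            mz.delta_w_recursion(np.ones(5), self.A, self.dt5, self.tau, 1.0)


class TestCalibration:
    def test_perfect_estimates_recover_identity(self):
        g = np.linspace(0.1, 0.9, 50)
        cal = mz.calibrate_and_error_cdf(g, g)
        assert cal.a == pytest.approx(1.0)
        assert cal.b == pytest.approx(0.0, abs=1e-12)
        assert cal.cdf(1e-12) == 1.0

    def test_linear_distortion_inverted_exactly(self):
        g = np.linspace(0.0, 1.0, 40)
        ghat = 0.5 * g + 0.1
        cal = mz.calibrate_and_error_cdf(ghat, g)
        assert cal.a == pytest.approx(2.0)
        assert cal.b == pytest.approx(-0.2)
        assert cal.abs_errors.max() < 1e-12

    def test_zero_variance_estimates_singular(self):
        with pytest.raises(np.linalg.LinAlgError):
            mz.calibrate_and_error_cdf(np.full(10, 0.5), np.linspace(0, 1, 10))

    def test_cdf_and_quantile_consistent(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0, 1, 500)
        ghat = g + rng.normal(0, 0.05, 500)
        cal = mz.calibrate_and_error_cdf(ghat, g)
        med = cal.quantile(0.5)
        assert cal.cdf(med) >= 0.5
        assert 0.02 < med < 0.06
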