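"""Vectorized simulation engine for the plastic spiking lattice.

The engine advances the full network state — membrane potentials,
two-exponential conductance filters per afferent class, refractory
clocks, recurrent plastic weights and cue-synapse weights — with an
exponential-Euler step (dt = 0.1 ms by default, resolving the 0.5 ms
synaptic rise time).  The numerically heavy inner loop is compiled with
numba.

Implementation choices that keep the default 40,000-neuron network
tractable:

* Conductances are integrated per neuron and per afferent class (two
  linear filters each) rather than per synapse; because all kernels share
  time constants this is exactly equivalent to summing per-synapse
  kernels.
* Static weights live on the translation-invariant offset stencil; the
  plastic recurrent component ``dW`` is a dense (maze neuron x offset)
  array, which is exhaustive because only maze neurons ever spike (all
  others are clamped), so every synapse with a nonzero ``dW`` has a maze
  presynaptic neuron.
* Spike pairing for STDP is all-to-all within the 100 ms cutoff via a
  ring buffer of recent spikes; simultaneous spikes (zero lag) contribute
  nothing.  The hard limit |dW| <= L|W0| is enforced at every update for
  recurrent synapses; cue synapses are exempt.
* Synaptic scaling multiplies every plastic weight by (1 - interval*dt/
  tau_s) once per ``scaling_interval`` steps while plasticity is enabled;
  the inter-trial gap (150 ms) is applied in closed form between trials.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import MazeSpec, NetworkConfig, PlasticityConfig, TaskConfig
from .lattice import LatticeGeometry, build_geometry
from .records import SpikeRecord
from . import tmaze
from .tmaze import CUES, CueSynapses, MazeMasks, TrialRecord, build_maze, wire_cues

__all__ = ["CircuitSimulator", "membrane_step", "NumericalInstabilityError"]


class NumericalInstabilityError(RuntimeError):
    """Raised when a membrane potential becomes non-finite."""


def membrane_step(V, g_E, g_I, config: NetworkConfig, dt: float):
    """One exponential-Euler membrane update for given total conductances.

    Closed-form relaxation toward the instantaneous fixed point
    ``V_inf = (g_L V_L + g_E V_E + g_I V_I) / g_tot`` with rate
    ``g_tot / C_m``; exact for conductances constant over the step.
    """
    g_tot = config.g_L + g_E + g_I
    v_inf = (config.g_L * config.V_L + g_E * config.V_E + g_I * config.V_I) / g_tot
    decay = np.exp(-g_tot * dt / (1000.0 * config.C_m))
    return v_inf + (V - v_inf) * decay


@njit(cache=True)
def _simulate(n, n_steps, dt, t0,
              # membrane / synapse constants
              cm_ms, g_L, V_L, V_E, V_I, V_th, V_R, tau_ref, F_E, F_I,
              tau_d, tau_r, gain,
              # mutable neuron state
              V, ref_until, xdE, xrE, xdI, xrI,
              clamped, is_inh,
              # static stencil
              off_dx, off_dy, wE0, wI0, offset_index, off_radius,
              # recurrent plastic weights
              maze_idx, dw_rec, limit_E, limit_I,
              # active-cue synapses
              cue_targets, cue_w0, cue_dw_active, cue_indptr, cue_order,
              cue_times, cue_dw_all,
              # drive schedule (per-ms snapshots, CSR)
              drive_indptr, drive_idx, drive_val, snap_of_step,
              # plasticity controls
              A_plus, A_minus, tau_plus, tau_minus, pair_cutoff,
              scale_factor, scaling_interval, stdp_on, scaling_on,
              # spike ring buffer and output
              rb_neuron, rb_time, spike_neuron, spike_time):
    """Advance the network ``n_steps`` steps; returns (n_spikes, status, bad_neuron, bad_step).

    status: 0 ok, 1 non-finite membrane potential, 2 spike buffer full.
    """
    N = n * n
    dec_d = np.exp(-dt / tau_d)
    dec_r = np.exp(-dt / tau_r)
    inv_dtau = 1.0 / (tau_d - tau_r)
    max_spikes = spike_neuron.shape[0]
    rb_cap = rb_neuron.shape[0]
    rb_start = 0
    rb_end = 0  # buffer holds [rb_start, rb_end) modulo capacity

    drive = np.zeros(N)
    cur_snap = -1
    cue_ptr = 0          # next cue spike to emit
    n_spikes = 0

    for step in range(n_steps):
        t1 = t0 + (step + 1) * dt

        # refresh the dense drive vector when the per-ms snapshot changes
        snap = snap_of_step[step]
        if snap != cur_snap:
            if cur_snap >= 0:
                for p in range(drive_indptr[cur_snap], drive_indptr[cur_snap + 1]):
                    drive[drive_idx[p]] = 0.0
            if snap >= 0:
                for p in range(drive_indptr[snap], drive_indptr[snap + 1]):
                    drive[drive_idx[p]] = drive_val[p]
            cur_snap = snap

        # decay conductance filters
        for i in range(N):
            xdE[i] *= dec_d
            xrE[i] *= dec_r
            xdI[i] *= dec_d
            xrI[i] *= dec_r

        # emit cue spikes due in this step: deliver conductance and pair (LTD)
        while cue_ptr < cue_times.shape[0] and cue_times[cue_ptr] <= t1:
            tc = cue_times[cue_ptr]
            for s in range(cue_targets.shape[0]):
                tgt = cue_targets[s]
                w = cue_w0[s] + cue_dw_active[s]
                if w > 0.0:
                    xdE[tgt] += w
                    xrE[tgt] += w
            if stdp_on:
                # pair the cue spike (pre) against recent grid spikes (post)
                j = rb_start
                while j != rb_end:
                    tb = rb_time[j]
                    lag = tc - tb      # pre after post -> depression
                    if 0.0 < lag <= pair_cutoff:
                        b = rb_neuron[j]
                        dec = -A_minus * np.exp(-lag / tau_minus)
                        for p in range(cue_indptr[b], cue_indptr[b + 1]):
                            cue_dw_active[cue_order[p]] += dec
                    j += 1
                    if j == rb_cap:
                        j = 0
            cue_ptr += 1

        # integrate membranes and detect threshold crossings
        step_first = n_spikes
        for i in range(N):
            if clamped[i]:
                V[i] = V_R
                continue
            if t1 < ref_until[i]:
                V[i] = V_R
                continue
            gE = F_E + gain * (xdE[i] - xrE[i]) * inv_dtau + drive[i]
            gI = F_I + gain * (xdI[i] - xrI[i]) * inv_dtau
            gtot = g_L + gE + gI
            vinf = (g_L * V_L + gE * V_E + gI * V_I) / gtot
            v = vinf + (V[i] - vinf) * np.exp(-gtot * dt / cm_ms)
            if not np.isfinite(v):
                return n_spikes, 1, i, step
            if v >= V_th:
                if n_spikes >= max_spikes:
                    return n_spikes, 2, i, step
                spike_neuron[n_spikes] = i
                spike_time[n_spikes] = t1
                n_spikes += 1
                V[i] = V_R
                ref_until[i] = t1 + tau_ref
            else:
                V[i] = v

        # deliver the new spikes through static + plastic recurrent weights
        for sidx in range(step_first, n_spikes):
            src = spike_neuron[sidx]
            sx = src // n
            sy = src % n
            m = maze_idx[src]
            inh = is_inh[src]
            for k in range(off_dx.shape[0]):
                tx = (sx + off_dx[k]) % n
                ty = (sy + off_dy[k]) % n
                tgt = tx * n + ty
                if inh:
                    w = wI0[k]
                else:
                    w = wE0[k]
                if m >= 0:
                    w += dw_rec[m, k]
                if w <= 0.0:
                    continue
                if inh:
                    xdI[tgt] += w
                    xrI[tgt] += w
                else:
                    xdE[tgt] += w
                    xrE[tgt] += w

        # STDP pairing of the new spikes
        if stdp_on and n_spikes > step_first:
            # advance the window start
            while rb_start != rb_end and t1 - rb_time[rb_start] > pair_cutoff:
                rb_start += 1
                if rb_start == rb_cap:
                    rb_start = 0
            for sidx in range(step_first, n_spikes):
                a = spike_neuron[sidx]
                ax = a // n
                ay = a % n
                ma = maze_idx[a]
                j = rb_start
                while j != rb_end:
                    b = rb_neuron[j]
                    tb = rb_time[j]
                    lag = t1 - tb
                    if 0.0 < lag <= pair_cutoff:
                        bx = b // n
                        by = b % n
                        dx = ax - bx
                        if dx > n // 2:
                            dx -= n
                        elif dx < -(n // 2):
                            dx += n
                        dy = ay - by
                        if dy > n // 2:
                            dy -= n
                        elif dy < -(n // 2):
                            dy += n
                        if -off_radius <= dx <= off_radius and -off_radius <= dy <= off_radius:
                            k_ab = offset_index[dx + off_radius, dy + off_radius]
                            if k_ab >= 0:
                                mb = maze_idx[b]
                                # potentiate synapse a <- b (pre b fired first)
                                if mb >= 0:
                                    lim = limit_I[k_ab] if is_inh[b] else limit_E[k_ab]
                                    w = dw_rec[mb, k_ab] + A_plus * np.exp(-lag / tau_plus)
                                    if w > lim:
                                        w = lim
                                    dw_rec[mb, k_ab] = w
                                # depress synapse b <- a (post b fired before pre a)
                                if ma >= 0:
                                    k_ba = offset_index[-dx + off_radius, -dy + off_radius]
                                    lim = limit_I[k_ba] if is_inh[a] else limit_E[k_ba]
                                    w = dw_rec[ma, k_ba] - A_minus * np.exp(-lag / tau_minus)
                                    if w < -lim:
                                        w = -lim
                                    dw_rec[ma, k_ba] = w
                    j += 1
                    if j == rb_cap:
                        j = 0
                # pair against past cue spikes (cue as pre -> potentiation)
                for c in range(cue_ptr - 1, -1, -1):
                    lag = t1 - cue_times[c]
                    if lag > pair_cutoff:
                        break
                    if lag > 0.0:
                        inc = A_plus * np.exp(-lag / tau_plus)
                        for p in range(cue_indptr[a], cue_indptr[a + 1]):
                            cue_dw_active[cue_order[p]] += inc

        # push the new spikes into the ring buffer
        for sidx in range(step_first, n_spikes):
            rb_neuron[rb_end] = spike_neuron[sidx]
            rb_time[rb_end] = t1
            rb_end += 1
            if rb_end == rb_cap:
                rb_end = 0
            if rb_end == rb_start:   # overwrite-protect: drop oldest
                rb_start += 1
                if rb_start == rb_cap:
                    rb_start = 0

        # homeostatic synaptic scaling
        if scaling_on and (step + 1) % scaling_interval == 0:
            for r_ in range(dw_rec.shape[0]):
                for k in range(dw_rec.shape[1]):
                    dw_rec[r_, k] *= scale_factor
            for c in range(cue_dw_all.shape[0]):
                for s in range(cue_dw_all.shape[1]):
                    cue_dw_all[c, s] *= scale_factor

    return n_spikes, 0, -1, -1


class CircuitSimulator:
    """Full spiking-circuit model of the cued T-maze task.

    One instance is one network realization: the lattice and maze are
    deterministic given the configuration, while the cue wiring is drawn
    from ``seed``.  Use :meth:`run_trial` (or :meth:`run_plan`) to execute
    a schedule of training and test trials; plastic state persists across
    trials.
    """

    def __init__(self, network: NetworkConfig | None = None,
                 plasticity: PlasticityConfig | None = None,
                 maze: MazeSpec | None = None,
                 task: TaskConfig | None = None,
                 seed: int = 0):
        self.network = network or NetworkConfig()
        self.plasticity = plasticity or PlasticityConfig()
        self.maze_spec = maze or MazeSpec()
        self.task = task or TaskConfig()
        self.seed = seed

        self.geometry: LatticeGeometry = build_geometry(self.network)
        self.masks: MazeMasks = build_maze(self.geometry, self.maze_spec)
        self.cues: CueSynapses = wire_cues(self.geometry, self.task,
                                           np.random.default_rng(seed))

        geo = self.geometry
        self._off_radius = int(np.floor(self.network.coupling_cutoff))
        L = self.plasticity.limit_factor
        self._limit_E = L * geo.w_pre_E
        self._limit_I = L * geo.w_pre_I

        maze_flat = np.flatnonzero(self.masks.maze)
        self.maze_neurons = maze_flat
        self.maze_idx = np.full(geo.n_neurons, -1, dtype=np.int64)
        self.maze_idx[maze_flat] = np.arange(len(maze_flat))
        self.dw_rec = np.zeros((len(maze_flat), geo.n_offsets))

        # CSR over cue synapses keyed by target neuron, one per cue
        self._cue_csr = []
        for c in range(2):
            order = np.argsort(self.cues.targets[c], kind="stable").astype(np.int64)
            sorted_t = self.cues.targets[c][order]
            indptr = np.searchsorted(sorted_t, np.arange(geo.n_neurons + 1)).astype(np.int64)
            self._cue_csr.append((indptr, order))

        self.reset_state()
        self.time = 0.0
        self._pending_gap_ms = 0.0

    # -- state ---------------------------------------------------------------

    def reset_state(self) -> None:
        """Reset membranes and conductance filters (plastic weights persist)."""
        N = self.geometry.n_neurons
        self.V = np.full(N, self.network.V_L)
        self.ref_until = np.full(N, -np.inf)
        self.xdE = np.zeros(N)
        self.xrE = np.zeros(N)
        self.xdI = np.zeros(N)
        self.xrI = np.zeros(N)

    def reset_plasticity(self) -> None:
        self.dw_rec[:] = 0.0
        self.cues.dw[:] = 0.0

    # -- drive schedule -------------------------------------------------------

    def _drive_schedule(self, kind: str, goal_arm, duration: float):
        """Per-ms drive snapshots as a CSR bundle + per-step snapshot ids."""
        task, masks = self.task, self.masks
        n = masks.grid_size
        dt = self.network.dt
        n_steps = int(round(duration / dt))
        steps_per_ms = max(1, int(round(1.0 / dt)))
        n_snaps = (n_steps + steps_per_ms - 1) // steps_per_ms

        xs, ys = np.divmod(self.maze_neurons, n)
        _, y_D = masks.start
        _, y_A = masks.decision_point
        t_A = (y_A - y_D) / task.rat_speed
        clamp = masks.non_maze.copy()
        if kind == "train":
            blocked = "L" if goal_arm == "R" else "R"
            clamp = clamp | masks.arm_mask(blocked)
        open_maze = ~clamp[self.maze_neurons]

        idx_chunks, val_chunks, indptr = [], [], [0]
        total = 0
        for s in range(n_snaps):
            t = (s * steps_per_ms + 0.5) * dt
            px, py = tmaze.rat_position(masks, kind, goal_arm, t, task)
            d2 = (xs - px) ** 2 + (ys - py) ** 2
            sel = (d2 <= task.place_field_radius ** 2) & open_maze
            amp = task.drive_amp
            if kind == "test" and t > t_A:
                amp *= task.hold_drive_factor
            vals = amp * np.exp(-d2[sel] / task.drive_sigma ** 2)
            idx_chunks.append(self.maze_neurons[sel])
            val_chunks.append(vals)
            total += int(sel.sum())
            indptr.append(total)
        snap_of_step = np.minimum(np.arange(n_steps) // steps_per_ms, n_snaps - 1)
        return (np.asarray(indptr, dtype=np.int64),
                np.concatenate(idx_chunks).astype(np.int64),
                np.concatenate(val_chunks),
                snap_of_step.astype(np.int64),
                clamp, n_steps)

    # -- trials ---------------------------------------------------------------

    def trial_duration(self, kind: str) -> float:
        masks, task = self.masks, self.task
        _, y_D = masks.start
        _, y_A = masks.decision_point
        t_A = (y_A - y_D) / task.rat_speed
        if kind == "train":
            return tmaze.trip_duration(masks, task) + 20.0
        return t_A + task.test_hold_ms

    def run_trial(self, trial: TrialRecord, record_spikes: bool = True,
                  cue_active: bool = True) -> SpikeRecord:
        """Simulate one trial; applies the inter-trial scaling decay afterwards.

        ``cue_active=False`` silences the cue neuron (control condition).
        """
        net, plast, task = self.network, self.plasticity, self.task
        geo = self.geometry
        duration = self.trial_duration(trial.kind)
        (drive_indptr, drive_idx, drive_val, snap_of_step,
         clamp, n_steps) = self._drive_schedule(trial.kind, trial.goal_arm, duration)

        t_on, t_off = tmaze.cue_window(self.masks, task, trial.kind)
        if cue_active:
            cue_times = tmaze.cue_spike_times(t_on, min(t_off, duration), task)
        else:
            cue_times = np.empty(0)
        cue_idx = CUES.index(trial.cue)
        indptr, order = self._cue_csr[cue_idx]

        plastic = trial.plasticity
        stdp_on = plastic and plast.enable_stdp
        scaling_on = plastic and plast.enable_scaling

        # inter-trial gap since the previous trial: closed-form scaling
        # relaxation, applied lazily so a lone test trial (rules frozen)
        # leaves the plastic state bit-identical.
        if plast.enable_scaling and self._pending_gap_ms > 0.0:
            steps_gap = self._pending_gap_ms / net.dt
            factor = plast.scaling_factor(net.dt) ** (steps_gap / plast.scaling_interval)
            self.dw_rec *= factor
            self.cues.dw *= factor
        self._pending_gap_ms = 0.0

        max_spikes = 500_000
        spike_neuron = np.empty(max_spikes, dtype=np.int64)
        spike_time = np.empty(max_spikes)
        rb_cap = 200_000
        rb_neuron = np.empty(rb_cap, dtype=np.int64)
        rb_time = np.empty(rb_cap)

        self.reset_state()
        n_spk, status, bad_neuron, bad_step = _simulate(
            geo.n, n_steps, net.dt, 0.0,
            1000.0 * net.C_m, net.g_L, net.V_L, net.V_E, net.V_I,
            net.V_th, net.V_R, net.tau_ref, net.F_E, net.F_I,
            net.tau_d, net.tau_r, geo.gain,
            self.V, self.ref_until, self.xdE, self.xrE, self.xdI, self.xrI,
            clamp.astype(np.uint8), self.geometry.is_inhibitory.astype(np.uint8),
            geo.off_dx, geo.off_dy, geo.w_pre_E, geo.w_pre_I,
            geo.offset_index, self._off_radius,
            self.maze_idx, self.dw_rec, self._limit_E, self._limit_I,
            self.cues.targets[cue_idx], self.cues.w0[cue_idx],
            self.cues.dw[cue_idx], indptr, order,
            cue_times.astype(float), self.cues.dw,
            drive_indptr, drive_idx, drive_val, snap_of_step,
            plast.A_plus if stdp_on else 0.0,
            plast.A_minus if stdp_on else 0.0,
            plast.tau_plus, plast.tau_minus, plast.pair_cutoff,
            plast.scaling_factor(net.dt) if scaling_on else 1.0,
            plast.scaling_interval, stdp_on, scaling_on,
            rb_neuron, rb_time, spike_neuron, spike_time)

        if status == 1:
            raise NumericalInstabilityError(
                f"non-finite membrane potential at neuron {bad_neuron}, "
                f"t = {(bad_step + 1) * net.dt:.2f} ms (trial {trial.index})"
            )
        if status == 2:
            raise NumericalInstabilityError(
                f"spike budget exhausted at t = {(bad_step + 1) * net.dt:.2f} ms "
                f"(trial {trial.index}): runaway activity"
            )

        # the gap after every trial is elapsed time for the training phase
        # (the test-trial window itself stays frozen); consumed at the
        # start of the next trial
        self._pending_gap_ms += task.trial_gap

        self.time += duration + task.trial_gap
        neuron = spike_neuron[:n_spk].copy() if record_spikes else np.empty(0, dtype=np.int64)
        t = spike_time[:n_spk].copy() if record_spikes else np.empty(0)
        return SpikeRecord(neuron=neuron, t=t, grid_size=geo.n, duration=duration,
                           trial_index=trial.index, kind=trial.kind, cue=trial.cue)

    def run_free(self, duration: float, plastic: bool = False) -> SpikeRecord:
        """Run with no rat drive and no cue (quiescence / stability checks)."""
        trial = TrialRecord(index=0, kind="test", cue="C2", goal_arm=None,
                            plasticity=plastic, blocked_arm=None, g=1.0, congruent=None)
        saved = self.task
        import dataclasses
        try:
            self.task = dataclasses.replace(saved, drive_amp=0.0,
                                            test_hold_ms=max(1.0, duration))
            rec = self.run_trial(trial, cue_active=False)
        finally:
            self.task = saved
        return rec

    def classify(self, spikes: SpikeRecord):
        """Outcome of a test-trial spike record under this task's windows."""
        from .sequences import classify_outcome
        t_on, _ = tmaze.cue_window(self.masks, self.task, "test")
        window = spikes.duration - t_on
        return classify_outcome(spikes, self.masks, spikes.cue, t_on, window,
                                self.task.spike_threshold)

    def run_plan(self, plan, progress: bool = False):
        """Run a full schedule; returns (outcomes on test trials, spike records)."""
        outcomes = []
        for rec in plan:
            spikes = self.run_trial(rec)
            if rec.kind == "test":
                outcomes.append(self.classify(spikes))
        return outcomes
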