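"""Pair-based STDP, homeostatic synaptic scaling and the hard weight limit.

The dynamic component of every coupling is a signed weight change
``dW(t)`` accumulated on top of the static weight ``W0``:

* **STDP** — every pair of pre/post spikes separated by ``Delta_t`` (post
  minus pre) within the pairing cutoff (5 tau = 100 ms) contributes
  ``+A_plus * exp(-Delta_t/tau_plus)`` when the post spike follows the pre
  spike, ``-A_minus * exp(-|Delta_t|/tau_minus)`` when it precedes it, and
  nothing at exactly zero lag.  Pairing is all-to-all within the cutoff.
* **Synaptic scaling** — once every ``scaling_interval`` integration steps
  every ``dW`` is multiplied by ``1 - interval*dt/tau_s``, i.e. weight
  changes relax exponentially back to the static baseline with timescale
  ``tau_s`` (7 s by default; absent firing, |dW| falls by a factor e in
  tau_s).
* **Hard limit** — recurrent weight changes are clamped to
  ``|dW| <= L * |W0|`` (L = 0.12), preventing the STDP positive feedback
  loop from running away.  Synapses from the external cue neurons are
  exempt (no feedback loop is possible through them).

The effective coupling entering the conductance dynamics is
``K = W0 + dW``.

This module is the reference implementation operating on an explicit
synapse dictionary; the lattice simulation engine (:mod:`.engine`)
implements the same rules in vectorized form over the offset stencil, and
the two are cross-checked in the test suite.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .config import PlasticityConfig

__all__ = ["stdp_window", "PlasticState"]


def stdp_window(delta_t, config: PlasticityConfig):
    """STDP window value for a post-minus-pre lag ``delta_t`` (ms).

    Antisymmetric when ``A_plus == A_minus`` and ``tau_plus == tau_minus``;
    identically zero at zero lag and beyond ``pair_cutoff``.
    """
    dt = np.asarray(delta_t, dtype=float)
    out = np.zeros_like(dt)
    pos = (dt > 0) & (dt <= config.pair_cutoff)
    neg = (dt < 0) & (-dt <= config.pair_cutoff)
    out = np.where(pos, config.A_plus * np.exp(-dt / config.tau_plus), out)
    out = np.where(neg, -config.A_minus * np.exp(dt / config.tau_minus), out)
    return out if out.ndim else float(out)


@dataclass
class PlasticState:
    """Explicit per-synapse plastic state over a fixed synapse set.

    ``w0`` maps (post, pre) to the static weight; ``dw`` holds the current
    signed change for the same keys.  Synapses in ``clamped`` are subject
    to the hard limit (recurrent synapses); cue synapses should be left
    out of ``clamped``.  ``recent`` is the spike buffer used for pairing.
    """

    config: PlasticityConfig
    w0: dict
    clamped: set
    dw: dict = field(default_factory=dict)
    recent: deque = field(default_factory=deque)

    def __post_init__(self) -> None:
        for key in self.w0:
            self.dw.setdefault(key, 0.0)
        self._last_t = -np.inf

    # -- STDP ---------------------------------------------------------------

    def update_on_spikes(self, spikes, t: float | None = None) -> None:
        """Pair the new spikes against the stored buffer and accumulate dW.

        ``spikes`` is an iterable of (neuron, time) with times monotone
        non-decreasing across calls.  Each new spike is paired with every
        stored spike of the opposite end of an existing synapse within the
        pairing cutoff; zero-lag pairs contribute nothing.
        """
        if not self.config.enable_stdp:
            for neuron, ts in spikes:
                self._push(neuron, ts)
            return
        for neuron, ts in spikes:
            if ts < self._last_t:
                raise ValueError("spike times must be monotone non-decreasing")
            self._last_t = ts
            self._prune(ts)
            for other, t_other in self.recent:
                lag = ts - t_other
                if lag == 0.0:
                    continue
                # new spike as POST on synapse (neuron <- other)
                key = (neuron, other)
                if key in self.dw:
                    self.dw[key] += stdp_window(lag, self.config)
                # new spike as PRE on synapse (other <- neuron)
                key = (other, neuron)
                if key in self.dw:
                    self.dw[key] += stdp_window(-lag, self.config)
            self._push(neuron, ts)

    def _push(self, neuron, ts) -> None:
        self.recent.append((neuron, ts))

    def _prune(self, now: float) -> None:
        cutoff = self.config.pair_cutoff
        while self.recent and now - self.recent[0][1] > cutoff:
            self.recent.popleft()

    # -- scaling ------------------------------------------------------------

    def apply_scaling(self, dt: float) -> None:
        """One scaling application: multiply every dW by (1 + C_s).

        ``dt`` is the integration step; the factor corresponds to
        ``scaling_interval`` steps of relaxation toward baseline.
        """
        if not self.config.enable_scaling:
            return
        factor = self.config.scaling_factor(dt)
        for key in self.dw:
            self.dw[key] *= factor

    # -- limit & effective coupling -----------------------------------------

    def clamp_and_combine(self) -> dict:
        """Clamp recurrent dW to the hard limit and return K = W0 + dW."""
        L = self.config.limit_factor
        for key in self.clamped:
            bound = L * abs(self.w0[key])
            dw = self.dw[key]
            if dw > bound:
                self.dw[key] = bound
            elif dw < -bound:
                self.dw[key] = -bound
        return {key: self.w0[key] + self.dw[key] for key in self.w0}


def brute_force_stdp(spike_train, synapses, config: PlasticityConfig) -> dict:
    """Independent oracle: double sum of the window over all spike pairs.

    ``spike_train`` is a list of (neuron, time); ``synapses`` an iterable
    of (post, pre) keys.  Used by the tests to validate the incremental
    accumulation; kept deliberately naive (O(S^2) per synapse).
    """
    out = {}
    for post, pre in synapses:
        total = 0.0
        for n_a, t_a in spike_train:
            if n_a != post:
                continue
            for n_b, t_b in spike_train:
                if n_b != pre:
                    continue
                total += stdp_window(t_a - t_b, config)
        out[(post, pre)] = total
    return out
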