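"""The two plasticity rules and their interplay on a toy spike chain.

A chain of seven neurons fires in order (5 ms apart).  Relative to the
middle neuron, STDP strengthens connections in the direction of travel
and weakens the reverse ones — the elementary step by which the circuit
learns paths.  Synaptic scaling then relaxes every change back toward
zero with a 7 s timescale, so old trials fade.
"""

import numpy as np

import mazesweep as mz
from mazesweep.plasticity import PlasticState, stdp_window

cfg = mz.PlasticityConfig()
print(f"window at +20 ms: {stdp_window(20.0, cfg):+.4e} (potentiation)")
print(f"window at -20 ms: {stdp_window(-20.0, cfg):+.4e} (depression)")
print(f"window at 0 / +120 ms: {stdp_window(0.0, cfg):+.1e} / "
      f"{stdp_window(120.0, cfg):+.1e} (zero lag and beyond the 5-tau cutoff)")

train = [(i, 5.0 * i) for i in range(7)]
ref = 3   # the middle neuron of the chain
pairs = {(i, ref): 5e-7 for i in range(7) if i != ref}
state = PlasticState(config=cfg, w0=pairs, clamped=set())
for spike in train:
    state.update_on_spikes([spike])
print("\nchange in coupling from the middle neuron to the others:")
for i in range(7):
    if i != ref:
        direction = "forward " if i > ref else "backward"
        print(f"  to neuron {i + 1} ({direction}): {state.dw[(i, ref)]:+.3e}")

factor = cfg.scaling_factor(0.1) ** (250.0 / (cfg.scaling_interval * 0.1))
print(f"\nscaling retains a fraction {factor:.5f} of dW per 250 ms trial "
      f"(exp(-0.25/7) = {np.exp(-0.25 / 7):.5f})")
print(f"scaling / STDP timescale ratio: {cfg.tau_s / cfg.tau_plus:.0f}")
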