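"""Build the default lattice and inspect its static structure.

The network is a 200 x 200 toroidal grid of conductance-based
integrate-and-fire neurons (inhibitory wherever both coordinates are
even).  Coupling is Gaussian in distance with a hard cutoff at D = 25
grid units, so each neuron collects input from 1960 neighbours.
"""

import numpy as np

import mazesweep as mz
from mazesweep.lattice import leak_steady_state

config = mz.NetworkConfig()
geometry = mz.build_geometry(config)

print(f"neurons: {geometry.n_neurons} "
      f"({geometry.n_excitatory} excitatory, {geometry.n_inhibitory} inhibitory)")
print(f"afferents of neuron (0, 0): {geometry.afferent_counts(0, 0)} (E, I)")
print(f"afferents of neuron (1, 0): {geometry.afferent_counts(1, 0)} (E, I)")

w = mz.static_weight((0, 0), (20, 0), "excitatory", config)
print(f"excitatory weight at distance 20: {w:.4e}  (= C_E * exp(-1))")

peak = mz.psc_kernel_peak_time(config.tau_d, config.tau_r)
print(f"synaptic kernel peaks {peak:.4f} ms after a spike")

v_rest = leak_steady_state(config)
print(f"resting potential under tonic inhibition: {v_rest:.2f} mV "
      f"(threshold {config.V_th:.0f} mV -> no spontaneous firing)")
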