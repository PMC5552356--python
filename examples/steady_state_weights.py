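"""Analytic tracker for the cue-synapse weight under STDP + scaling.

Per training trial a cue synapse onto the congruent arm gains
A+ * exp(-dt5/tau+) with probability g_n and the whole change decays by
the scaling factor r.  Iterating that recursion converges to the fixed
point F * g_bar with F = A+ exp(-dt5/tau+)/(1 - r): the steady-state
weight change is proportional to the (recent-history) association
probability — the synapse itself encodes the posterior the sweep reads
out at the decision point.
"""

import numpy as np

import mazesweep as mz

A_plus, dt5, tau_plus = 1.2e-9, 5.0, 20.0
r = np.exp(-0.25 / 7.0)          # scaling decay over one 250 ms trial cycle
F = A_plus * np.exp(-dt5 / tau_plus) / (1 - r)

g_const = np.full(400, 0.7)
series = mz.delta_w_recursion(g_const, A_plus, dt5, tau_plus, r)
print(f"per-trial decay r = {r:.5f},  gain factor F = {F:.4e}")
print(f"recursion at constant g=0.7 after 400 trials: {series[-1]:.6e}")
print(f"closed-form fixed point F * 0.7:              {F * 0.7:.6e}")

rng = np.random.default_rng(3)
g_walk = mz.generate_g_sequence("gaussian_walk", 600, rng=rng, Q=2e-3)
g_bar, dw_ss = mz.delta_w_ss_tracker(g_walk, A_plus, dt5, tau_plus, r, N=50)
corr = np.corrcoef(g_bar[50:], dw_ss[50:])[0, 1]
print(f"\non a drifting association, corr(dW_ss, trailing-mean g) = {corr:.3f}")
print("(identically 1: the steady-state weight change simply rescales the")
print(" trailing 50-trial mean of the association probability)")
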