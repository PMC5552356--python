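# Methods

## Model

The circuit is a two-dimensional conductance-based integrate-and-fire
network on an `n × n` toroidal grid (default n = 200; 40,000 neurons).
A neuron is inhibitory iff both of its integer coordinates are even
(25%), excitatory otherwise. Membrane parameters: C_m = 1 µF/cm²,
g_L = 50 µS/cm², V_L = V_R = −70 mV, V_E = 0 mV, V_I = −80 mV,
V_th = −55 mV, refractory period 5 ms. A tonic inhibitory conductance
F_I = 15 µS/cm² holds the quiescent resting potential at −72.3 mV, so
the network never fires spontaneously.

Static coupling from a presynaptic neuron of class λ at toroidal
distance d is `C_λ exp(−d²/d_λ²)` for 0 < d ≤ D and zero beyond
(C_E = 5e-7, C_I = 2.4e-7 weight units; d_E = 20, d_I = 90; D = 25).
Self-connections are excluded, giving every neuron exactly 1960
afferents. The excitatory/inhibitory split of those afferents is
1470/490 exactly as the average over the four lattice parity classes;
per neuron it varies by up to ±6 with parity (no cutoff convention
makes it exactly 1470/490 for every neuron).

Synaptic input enters through a normalized difference-of-exponentials
kernel (τ_r = 0.5 ms, τ_d = 2 ms, unit integral). Because all synapses
share the kernel time constants, conductances are integrated with two
exact linear filters per neuron and per afferent class rather than per
synapse — algebraically identical to summing per-synapse kernels.
Integration uses exponential-Euler steps of dt = 0.1 ms (the rise time
must be resolved); spike threshold is tested after the step and all
crossings in a step fire together.

### Weight units and the conductance gain

The published weight scales (C_E = 5e-7 etc.) are in model units with
no stated conversion to µS/cm²; taken literally they produce
dynamically inert input. The engine therefore applies a single gain
converting weight units to µS/cm². The gain is parameterized through
`exc_input_scale`: the summed static excitatory afferent weight of a
neuron maps to `exc_input_scale` µS/cm², which makes the operating
point invariant to the footprint size (important for scaled models).
The default, 1220 µS/cm², was calibrated once against three
qualitative anchors: a quiescent network stays silent, the moving
place-field bump fires every neuron on the rat's path one-to-few
times, and a *trained but uncued* network does not launch arm
sequences while a trained-and-cued one does. All weight ratios
(STDP amplitude to static weight, hard limit, cue weights) are the
published ones; only this overall conversion is the package's.

## Plasticity

Every synapse (recurrent of both classes, and cue) carries a signed
plastic change ΔW on top of W0:

* **STDP** — all-to-all pairing within a 100 ms (5τ) cutoff:
  `+A₊ exp(−Δt/τ₊)` when the postsynaptic spike trails the presynaptic
  one by Δt, `−A₋ exp(−|Δt|/τ₋)` for the reverse order, zero at exact
  coincidence. A₊ = A₋ = 1.2e-9, τ₊ = τ₋ = 20 ms.
* **Synaptic scaling** — once every 100 integration steps (10 ms),
  every ΔW is multiplied by `1 − 10 ms/τ_s` with τ_s = 7 s:
  exponential relaxation toward the static baseline. The constant is
  negative by construction (weights *reset toward* their original
  values). Inter-trial gaps (150 ms) are applied in closed form,
  lazily at the start of the next trial so that a lone test trial
  (both rules frozen) leaves the plastic state bit-identical.
* **Hard limit** — recurrent changes are clamped to |ΔW| ≤ 0.12 |W0|
  at every update. The printed form of the constraint (|W(t)| ≤
  0.12 |W(0)|) would shrink all weights eight-fold; the stated intent
  ("prevent connection strengths from being modified too significantly
  from their initial values") fixes the ΔW reading. Cue synapses are
  exempt: no feedback loop can run through them.

The engine implements these rules in vectorized form over the offset
stencil; a dictionary-based reference implementation
(`plasticity.PlasticState`) exists for small systems and the two are
cross-checked against each other and against a brute-force pair double
sum in the tests.

## T-maze task

The maze is an 11-wide corridor: a stem of 60 grid units from the
start D to the decision point A and two 40-unit arms (half/double
sizes supported). Neurons with place fields outside the maze are
permanently voltage-clamped and never fire. The model rat moves at
1 grid unit/ms, so a traversal takes ~105 ms; trials are separated by
150 ms. Its drive is a Gaussian-profile excitatory conductance
injection (amplitude 50 µS/cm², width σ = 12.5 at full scale)
truncated at the place-field radius. The amplitude matters: path
neurons must reach threshold in the few milliseconds the moving bump
covers them (at 30 µS/cm² much of the path stays silent and nothing is
learned), yet fire only ~1–2 spikes each so that the scaling
equilibrium of the recurrent ΔW sits near half the hard limit rather
than pinned at it (a pinned equilibrium reproduces the no-scaling
pathology even with scaling on).

On a training trial the goal arm is drawn cue-congruent with
probability g_n (cue C1 ↔ left, C2 ↔ right, alternating across
trials), the other arm is voltage-clamped, and the rat runs to the
goal with both plasticity rules active. A frozen test trial follows
each training trial: no arm blocked, the rat halts at A for a 100 ms
observation window, plasticity off.

Each cue neuron projects N = 40,000 synapses to postsynaptic targets
drawn uniformly with replacement, with initial weights sampled from
the efferent-weight population of an in-grid excitatory neuron. N is
kept at 40,000 at every scale (the "one synapse per neuron on
average" gloss holds only for the full-size grid). The cue fires
regularly at 400 Hz while the rat is near the decision point: from
cue-zone entry (20 units before A) until 10 ms after the rat passes A
on training trials, and throughout the hold on test trials (the rat is
parked at A). This single position-tied rule matters mechanistically:
a cue that keeps firing after the sequence has moved on pairs
post-before-pre with the very neurons the early pairings potentiated,
and the resulting depression cancels the learned asymmetry; a cue that
stops with the tone leaves pure potentiation along the goal arm. At
200 Hz the cue pathway carries too little conductance to gate the
sweep, hence the 400 Hz default.

### Outcome classification

Within the observation window the terminal 10 columns of each arm
(scaled with the maze) are the goal zones. A test trial is *correct*
if ≥ 5 spikes land in the cue-associated goal zone and < 5 in the
other, *wrong arm* in the mirror case, *split* when both zones exceed
threshold and *none* otherwise. "Correct" always refers to the cue's
nominal association (C2 → right); under time-varying protocols the
congruent-choice rate is the circuit's estimate of g_n.

## Scaled models

Scaled experiments shrink **all** spatial quantities together: grid,
maze, coupling cutoff, footprints, place-field radius and drive width.
Keeping the coupling ranges fixed while halving the maze puts the goal
zones inside the decision-point bump's recurrent halo and produces
spurious "split" classifications; the uniformly scaled model preserves
the geometric separations that make the outcome taxonomy meaningful.
The gain normalization (above) keeps the dynamic operating point fixed
across scales. The corridor width stays at 11 — at half scale it then
matches "slightly smaller than the place field", with the field
diameter comparable to the coupling range.

The scaled-down study conditions used by the test suite are: half
scale (100 × 100 grid), 4 network realizations, 60–80 training trials.
One realization of 40 trials takes ~5 s on one core. The learning
curve at this scale rises from 0 and saturates at 1.0 over the last
trials; the sub-unity asymptote (~0.8) reported for the full-size
network is an ensemble property at that size and is left to full-scale
runs, which use the identical code path (`scale=1.0`).

## Estimators

Observations are y = 1 iff the goal fell on the cue-congruent arm;
the likelihood is p(y=1|g) = g. (The source text labels arms
inconsistently between its likelihood and its worked example; the
congruency convention is the unique reading under which the printed
estimate 0.5 at trial 200 of the switch protocol is consistent.)

* **Simple recursive Bayes** — flat prior; Beta posterior; the point
  estimate is the count ratio `#congruent/n` (the printed formula is
  the mean-like ratio even though the text calls it maximum
  likelihood; the ratio is implemented). Permutation-invariant.
* **Discounted Bayes** — the previous posterior is raised to the
  power α = 0.99 before each update; expanding the recursion gives
  geometric weights α^k on the evidence from k trials back. (A printed
  expansion with arithmetic exponents kα contradicts the recursion and
  its own monotonicity chain; the geometric form is implemented.)
  Computed on a 1001-point grid over [0, 1] with MAP read-off, ties
  broken toward 0.5; a closed-form discounted-count implementation is
  kept as an independent cross-check.
* **Kalman filter** — scalar recursion exactly as printed, parameters
  named by their role in the filter (Q the measurement-noise
  covariance in the gain, Z the state noise added to the error
  covariance; the source swaps the symbols between the filter and the
  generative model). Defaults ĝ₀ = 0.5, Σ₀ = 0.1. For the Bernoulli
  task observations the tuned measurement noise is Q = 0.16, the mean
  Bernoulli variance E[g(1−g)] under the Q = 2e-5 random-walk prior,
  measured over independent streams.

On the random-walk protocol the tuned Kalman filter and discounted
Bayes have nearly identical error distributions (medians ~0.02–0.03);
comparisons pool absolute calibrated errors over several independent
streams because single-stream medians differ by less than their
sampling noise.

The g-sequence generator provides the three regimes: constant,
step-switch (0 for the first 100 trials, then 1) and a Gaussian random
walk with per-trial variance Q = 2e-5 started at g = 1/2 and clipped
to [0, 1] (probabilities must stay valid; the clip is the only
departure from the pure walk).

## Numerical and design notes

* Exponential-Euler is exact for conductances frozen within a step;
  the membrane leak time constant (20 ms) and synaptic rise (0.5 ms)
  are both well resolved at dt = 0.1 ms.
* The conductance filters are exact discrete solutions of the kernel
  ODEs; a fresh spike contributes zero conductance at its arrival step
  and the kernel's unit area is conserved to second order in dt
  (~8e-4 at dt = 0.1 ms).
* Simultaneous spikes contribute no STDP (zero lag) and are paired
  against the buffer before being added to it.
* The directional bias measure sums x-displacement-weighted efferent
  couplings per source neuron with minimal-image displacements; for
  the isotropic static lattice it cancels to rounding error. Its
  "theoretical maximum" depends on an unstated normalization and is
  deliberately not asserted anywhere.
* Trailing-mean window for the steady-state weight tracker: N = 50
  previous trials (all available history early on).
* Realizations are seeded from `SeedSequence(master).spawn(r)`;
  results are bit-reproducible for fixed dt and realization count and
  independent of execution order.

## Limitations

* The conductance gain and drive amplitude are calibrated, not
  derived; other (gain, drive) pairs reproduce the same phenomenology
  in a band around the defaults, but far outside it the circuit either
  stays silent or splits.
* The synthetic task generator is the idealized protocol: perfectly
  regular trial timing, noiseless rat trajectory, deterministic cue
  trains and no reward signal. Passing tests show the mechanism is
  sufficient under these conditions, not that it is robust to
  biological variability in any of them.
* At desk scale the trained circuit is essentially deterministic per
  wiring realization; the graded correct-rate asymptote seen in large
  networks emerges only at sizes the test suite does not run.
* Axonal delays, separate receptor kinetics, firing-rate-based scaling
  and reward modulation are out of scope.
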