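# mazesweep

A spiking neural circuit model of goal-directed choice in a cued T-maze,
together with the probabilistic estimators it is benchmarked against.

Rodents trained on a cued T-maze show *internally generated sequences*
(IGS) in hippocampal recordings: as the animal pauses at the decision
point, place-cell activity sweeps forward along the arm it is about to
choose. `mazesweep` implements a mechanistic account of how such sweeps
can be learned and used to make choices: a 2D lattice of
conductance-based integrate-and-fire neurons whose synapses combine
fast spike-timing dependent plasticity (STDP) with slow homeostatic
synaptic scaling. During training, a moving activity bump (the
externally generated sequence tracking the model rat) lets STDP learn
the maze paths and lets each auditory-cue neuron acquire weights biased
toward its associated arm; on test trials, the cue launches a forward
sweep from the decision point down one arm, which is scored as the
circuit's choice. Because scaling continuously relaxes weight changes
toward baseline, the circuit forgets old contingencies and can track a
cue-goal association probability `g_n` that drifts or switches over
time — the same problem the package's recursive-Bayes, discounted-Bayes
and Kalman-filter baselines solve explicitly.

## Model in brief

Membrane dynamics of the neuron at lattice site (i, j):

    C dV/dt = -g_L (V - V_L) - g_E (V - V_E) - g_I (V - V_I)

with spikes at −55 mV, reset to −70 mV and a 5 ms refractory period.
Synaptic conductances are driven through a normalized
difference-of-exponentials kernel (rise 0.5 ms, decay 2 ms) by afferent
spikes weighted with the effective coupling `K = W0 + ΔW`, where the
static coupling is Gaussian in toroidal distance,

    W0(d) = C_λ exp(-d² / d_λ²)   for 0 < d ≤ D = 25,

(λ the presynaptic class; inhibitory neurons sit where both coordinates
are even) and the plastic part ΔW evolves by

* pair-based STDP: `±A exp(-|Δt|/τ)` per pre/post spike pair within
  5τ = 100 ms (A = 1.2e-9, τ = 20 ms);
* synaptic scaling: multiplicative relaxation of ΔW toward zero with
  timescale 7 s (350× slower than STDP) applied every 100 steps;
* a hard limit |ΔW| ≤ 0.12 |W0| on recurrent synapses (cue synapses,
  which cannot form feedback loops, are exempt).

The estimators of `g_n` are: the Beta-posterior count-ratio estimator
(order-blind), its discount-modified variant
`p(g|Y_n) ∝ p(y_n|g) p(g|Y_{n-1})^α` with α = 0.99 (order-sensitive,
the synaptic-scaling analogue), and the scalar Kalman filter
`ĝ' = (1-K) ĝ + K y`, `K = Σ/(Σ+Q)`.

## Worked example

`examples/tracking_a_switched_association.py` reverses the cue-goal
association after 100 trials and compares the estimators at trial 200:

```
true association at trial 200:        g = 1.00
simple recursive Bayes estimate:      0.5000
discounted Bayes (alpha=0.99):        0.7320
discounted Bayes on the REVERSED run: 0.2680
```

The count-ratio estimate is stuck at the overall count ratio 0.5 and is
identical for any trial order; the discounted posterior forgets the
pre-switch block geometrically and tracks the new association — the
statistical behaviour the plastic circuit reproduces mechanistically.

`examples/tmaze_learning_curve.py` trains one half-scale circuit
realization for 30 trials (a ~minute of compute):

```
trial  outcome    spikes in assoc/other goal zone
    3  none          0 / 0
   12  none          0 / 0
   24  correct       5 / 1
   30  correct       7 / 1

correct tests: 6/30 (last ten: 6/10)
mean C2 cue dW: left arm 0.00e+00, right arm 6.43e-08
```

Early test trials launch no sequence; once the C2 cue's weights onto the
right arm have grown (left arm exactly zero), the cue-triggered sweep
reliably reaches the right goal zone. The other scripts in `examples/`
cover the lattice structure, the plasticity rules, random-walk tracking
and the analytic steady-state weight tracker. A thin CLI mirrors the
library (`mazesweep reproduce fig3 --scale 0.5 --realizations 4`,
`mazesweep baselines --protocol step_switch`, `mazesweep simulate
spec.yaml`, `mazesweep analyze <bundle>`).

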