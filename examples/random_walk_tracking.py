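"""Track a drifting association with the Kalman filter and discounted Bayes.

The association g_n performs a clipped Gaussian random walk (variance
2e-5 per trial); each trial yields a single Bernoulli observation.  Both
estimators are linearly recalibrated (least squares) and compared through
the cumulative distribution of their absolute errors.
"""

import numpy as np

import mazesweep as mz

root = np.random.SeedSequence(7)
g_rng, y_rng = (np.random.default_rng(s) for s in root.spawn(2))
g = mz.generate_g_sequence("gaussian_walk", 5000, rng=g_rng, Q=2e-5)
y = mz.simulate_cue_goal_trials(g, y_rng)

kal = mz.kalman_filter(y, Q=0.16, Z=2e-5)   # Q = mean Bernoulli variance
disc = mz.discounted_bayes(y, alpha=0.99)

burn = 200
cal_k = mz.calibrate_and_error_cdf(kal.estimates[burn:], g[burn:])
cal_d = mz.calibrate_and_error_cdf(disc.estimates[burn:], g[burn:])

print(f"trials: {len(y)}   walk range of g: [{g.min():.3f}, {g.max():.3f}]")
print(f"steady-state Kalman gain: {kal.gains[-1]:.4f}")
print(f"median |error|  kalman: {cal_k.quantile(0.5):.4f}   "
      f"discounted Bayes: {cal_d.quantile(0.5):.4f}")
print(f"P(|error| < 0.03)  kalman: {cal_k.cdf(0.03):.2f}   "
      f"discounted Bayes: {cal_d.cdf(0.03):.2f}")
print(f"P(|error| < 0.05)  kalman: {cal_k.cdf(0.05):.2f}   "
      f"discounted Bayes: {cal_d.cdf(0.05):.2f}")
print()
print("Both trackers smooth over ~100 trials and are near-indistinguishable")
print("on a single stream; pooled over many streams the tuned Kalman filter")
print("is marginally the more accurate of the two.")
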