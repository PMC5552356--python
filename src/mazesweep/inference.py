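"""Probabilistic estimators of the cue-goal association probability g_n.

On trial ``n`` the goal lies on the cue-congruent arm (right for cue C2,
left for C1) with probability ``g_n``.  A trial outcome is encoded as the
binary observation ``y_n`` with ``y = 1`` iff the goal was congruent, so
the likelihood is ``p(y=1 | g) = g``.  Three estimators of ``g_n`` are
provided for head-to-head comparison with the spiking circuit:

* **Simple recursive Bayes** — Beta posterior under a flat prior; the
  point estimate is the count ratio ``#congruent / n``.  It depends only
  on the observation multiset, never on trial order, which is why it fails
  after an association switch.
* **Discounted Bayes** — the previous posterior is raised to a power
  ``alpha < 1`` before each update, geometrically discounting old
  evidence; equivalently, exponentially discounted congruent/incongruent
  counts.  Order-sensitive, mirroring the resetting effect of synaptic
  scaling.
* **1-D Kalman filter** — scalar predict/update recursion with gain
  ``K = Sigma / (Sigma + Q)``; optimal for a Gaussian random walk in
  ``g_n`` observed with Gaussian noise, and near-optimal for the Bernoulli
  observations the task actually produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError

__all__ = [
    "simulate_cue_goal_trials",
    "simple_bayes",
    "discounted_bayes",
    "discounted_count_estimates",
    "kalman_filter",
    "BayesResult",
    "KalmanResult",
]

#: number of grid points for the posterior over g in [0, 1]
GRID_POINTS = 1001


def _grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, GRID_POINTS)


def simulate_cue_goal_trials(g_sequence, rng) -> np.ndarray:
    """Draw binary observations y_n ~ Bernoulli(g_n).

    ``y = 1`` marks a congruent trial (goal on the cue-congruent arm).
    This Bernoulli channel is what the circuit and the estimators actually
    observe; the Gaussian measurement model of the Kalman derivation is an
    approximation to it.
    """
    g = np.asarray(g_sequence, dtype=float)
    if np.any((g < 0) | (g > 1)):
        raise ValueError("g values must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    return (rng.random(g.shape) < g).astype(np.int64)


@dataclass
class BayesResult:
    """Posterior over g on a fixed grid plus per-trial point estimates."""

    grid: np.ndarray
    posterior: np.ndarray          # final posterior, sums to 1 on the grid
    estimates: np.ndarray          # point estimate after each trial

    @property
    def estimate(self) -> float:
        return float(self.estimates[-1])


def simple_bayes(observations) -> BayesResult:
    """Recursive Bayes under a constant-g assumption and flat prior.

    The posterior after n trials is Beta(n_cong + 1, n_incong + 1) (here
    normalized on the evaluation grid); the point estimate is the count
    ratio ``n_cong / n``, the form the recursion's maximum-likelihood
    reading reduces to.  Permutation-invariant in the observations.
    """
    y = np.asarray(observations, dtype=np.int64)
    if y.size == 0:
        raise ValueError("estimate undefined for an empty observation sequence")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("observations must be binary (1 = congruent)")
    g = _grid()
    n_cong = np.cumsum(y)
    n = np.arange(1, y.size + 1)
    estimates = n_cong / n
    a, b = int(n_cong[-1]), int(n[-1] - n_cong[-1])
    with np.errstate(divide="ignore"):
        # guard 0 * log(0) at the grid boundary for degenerate counts
        log_post = np.zeros_like(g)
        if a:
            log_post += a * np.log(g)
        if b:
            log_post += b * np.log1p(-g)
    log_post -= log_post.max()
    post = np.exp(log_post)
    post /= post.sum()
    return BayesResult(grid=g, posterior=post, estimates=estimates)


def discounted_bayes(observations, alpha: float) -> BayesResult:
    """Discount-modified recursive Bayes on the posterior grid.

    Each update raises the previous posterior to the power ``alpha``
    (0 < alpha <= 1) before multiplying in the current likelihood, so
    evidence from k trials ago enters with exponent ``alpha**k``.  With
    ``alpha = 1`` this is exactly :func:`simple_bayes`.  The per-trial
    point estimate is the grid MAP (ties broken toward g = 0.5).
    """
    if not (0.0 < alpha <= 1.0):
        raise ConfigurationError("discount factor must satisfy 0 < alpha <= 1")
    y = np.asarray(observations, dtype=np.int64)
    if y.size == 0:
        raise ValueError("estimate undefined for an empty observation sequence")
    g = _grid()
    with np.errstate(divide="ignore"):
        log_g = np.log(g)
        log_1mg = np.log1p(-g)
    log_post = np.zeros_like(g)   # flat prior
    estimates = np.empty(y.size)
    for i, obs in enumerate(y):
        log_post = alpha * log_post + (log_g if obs else log_1mg)
        log_post -= log_post.max()
        estimates[i] = _map_estimate(g, log_post)
    post = np.exp(log_post)
    post /= post.sum()
    return BayesResult(grid=g, posterior=post, estimates=estimates)


def _map_estimate(g: np.ndarray, log_post: np.ndarray) -> float:
    best = np.flatnonzero(log_post == log_post.max())
    if len(best) == 1:
        return float(g[best[0]])
    # break ties toward 0.5
    return float(g[best[np.argmin(np.abs(g[best] - 0.5))]])


def discounted_count_estimates(observations, alpha: float) -> np.ndarray:
    """Closed-form discounted-count ratio S_cong / (S_cong + S_incong).

    ``S_cong = sum_k alpha^k [y_{n-k} = 1]`` and likewise for incongruent
    observations; equals the grid MAP of :func:`discounted_bayes` up to
    grid resolution.  Exposed separately so the two routes can be
    cross-checked.
    """
    if not (0.0 < alpha <= 1.0):
        raise ConfigurationError("discount factor must satisfy 0 < alpha <= 1")
    y = np.asarray(observations, dtype=float)
    s_cong = 0.0
    s_inc = 0.0
    out = np.empty(y.size)
    for i, obs in enumerate(y):
        s_cong = alpha * s_cong + obs
        s_inc = alpha * s_inc + (1.0 - obs)
        out[i] = s_cong / (s_cong + s_inc)
    return out


@dataclass
class KalmanResult:
    estimates: np.ndarray     # ghat_1 .. ghat_n (after each observation)
    covariances: np.ndarray   # Sigma after each observation
    gains: np.ndarray         # K(n) used at each observation

    @property
    def estimate(self) -> float:
        return float(self.estimates[-1])


def kalman_filter(observations, Q: float, Z: float,
                  g0: float = 0.5, sigma0: float = 0.1) -> KalmanResult:
    """Scalar Kalman filter for a slowly drifting association probability.

    Parameters follow their role in the filter recursion: ``Q`` is the
    measurement-noise covariance (entering the gain), ``Z`` the state-noise
    covariance added to the error covariance each trial:

    ``ghat_{n+1} = (1 - K_n) ghat_n + K_n y_n``;
    ``Sigma_{n+1} = (1 - K_n)^2 Sigma_n + K_n^2 Q + Z``;
    ``K_n = Sigma_n / (Sigma_n + Q)``.
    """
    if Q < 0 or Z < 0 or sigma0 < 0:
        raise ConfigurationError("Q, Z and sigma0 must be non-negative")
    y = np.asarray(observations, dtype=float)
    if Q == 0.0 and sigma0 == 0.0:
        raise ConfigurationError("gain undefined for Q = 0 with Sigma = 0")
    ghat = float(g0)
    sigma = float(sigma0)
    estimates = np.empty(y.size)
    covariances = np.empty(y.size)
    gains = np.empty(y.size)
    for i, obs in enumerate(y):
        gain = sigma / (sigma + Q)
        ghat = (1.0 - gain) * ghat + gain * obs
        sigma = (1.0 - gain) ** 2 * sigma + gain ** 2 * Q + Z
        estimates[i] = ghat
        covariances[i] = sigma
        gains[i] = gain
    return KalmanResult(estimates=estimates, covariances=covariances, gains=gains)
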