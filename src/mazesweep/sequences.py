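"""Analysis of internally generated sequences and learned weight structure.

Covers the per-trial outcome taxonomy (correct / wrong arm / split /
none), correct-rate learning curves with SEM across realizations, the
directional connection-bias measure, the cue-weight asymmetry profile
across maze columns, the analytic steady-state tracker for the cue-synapse
weight change, and the linear calibration + error-CDF comparison used to
benchmark estimators of the cue-goal association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import LatticeGeometry, toroidal_delta
from .records import SpikeRecord
from .tmaze import CUE_ARM, CueSynapses, MazeMasks

__all__ = [
    "OutcomeRecord",
    "classify_outcome",
    "correct_rate_curve",
    "bias_measure",
    "bias_from_coo",
    "cue_asymmetry_profile",
    "delta_w_recursion",
    "delta_w_ss_tracker",
    "CalibrationResult",
    "calibrate_and_error_cdf",
]

OUTCOME_CLASSES = ("correct", "wrong_arm", "split", "none")


@dataclass
class OutcomeRecord:
    """Classification of one test trial from its goal-zone spiking."""

    trial_index: int
    outcome: str
    n_spikes_assoc: int
    n_spikes_other: int
    first_spike_assoc: float | None
    first_spike_other: float | None

    @property
    def correct(self) -> bool:
        return self.outcome == "correct"


def classify_outcome(spikes: SpikeRecord, masks: MazeMasks, cue: str,
                     cue_onset: float, window: float = 100.0,
                     threshold: int = 5) -> OutcomeRecord:
    """Classify a test trial by goal-zone spike counts after cue onset.

    A trial is *correct* when at least ``threshold`` spikes land in the
    goal zone of the cue-associated arm within ``window`` ms of cue onset
    while the opposite goal zone stays below threshold; the mirror case is
    *wrong_arm*; both above threshold is *split* (the sequence propagated
    down both arms); neither is *none* (no sequence reached a goal).
    """
    if cue_onset < 0 or cue_onset + window > spikes.duration + 1e-9:
        raise ValueError(
            f"classification window [{cue_onset}, {cue_onset + window}] outside "
            f"trial duration {spikes.duration}"
        )
    assoc_arm = CUE_ARM[cue]
    other_arm = "L" if assoc_arm == "R" else "R"
    win = spikes.in_window(cue_onset, cue_onset + window)

    def zone_stats(arm):
        zone = masks.goal_mask(arm)
        sel = zone[win.neuron]
        times = win.t[sel]
        return int(sel.sum()), (float(times.min()) if len(times) else None)

    n_assoc, first_assoc = zone_stats(assoc_arm)
    n_other, first_other = zone_stats(other_arm)
    if n_assoc >= threshold and n_other < threshold:
        outcome = "correct"
    elif n_other >= threshold and n_assoc < threshold:
        outcome = "wrong_arm"
    elif n_assoc >= threshold and n_other >= threshold:
        outcome = "split"
    else:
        outcome = "none"
    return OutcomeRecord(trial_index=spikes.trial_index, outcome=outcome,
                         n_spikes_assoc=n_assoc, n_spikes_other=n_other,
                         first_spike_assoc=first_assoc, first_spike_other=first_other)


def correct_rate_curve(outcomes) -> pd.DataFrame:
    """Per-trial mean correct rate and SEM across realizations.

    ``outcomes`` is a sequence of realizations, each a sequence of
    :class:`OutcomeRecord` (or booleans) of identical length.  SEM is the
    sample standard deviation (ddof=1) over realizations divided by
    sqrt(#realizations).
    """
    rows = []
    for realization in outcomes:
        rows.append([rec.correct if isinstance(rec, OutcomeRecord) else bool(rec)
                     for rec in realization])
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged realization lengths: {sorted(lengths)}")
    if len(rows) < 2:
        raise ValueError("need at least 2 realizations for a SEM")
    mat = np.asarray(rows, dtype=float)
    rate = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    return pd.DataFrame({
        "trial": np.arange(1, mat.shape[1] + 1),
        "rate": rate,
        "sem": sem,
        "n_realizations": mat.shape[0],
    })


def bias_measure(geometry: LatticeGeometry, dw=None, maze_neurons=None) -> np.ndarray:
    """Directional bias |sum over targets of x-displacement * K| per neuron.

    For every source neuron the efferent effective couplings ``K = W0 +
    dW`` are summed weighted by the (minimal-image) x-displacement to each
    target; isotropic weights cancel exactly, so nonzero values flag a
    learned left/right asymmetry.  ``dw`` is the engine's plastic-weight
    array of shape (len(maze_neurons), n_offsets); with ``dw=None`` the
    static-only bias (identically zero) is returned.
    """
    n_tot = geometry.n_neurons
    bias = np.zeros(n_tot)
    dx = geometry.off_dx.astype(float)
    # static part: sum_k dx_k * w_k is zero by symmetry for either class,
    # but compute it anyway so the cancellation is exercised, not assumed
    static_E = float(np.dot(dx, geometry.w_pre_E))
    static_I = float(np.dot(dx, geometry.w_pre_I))
    bias += np.where(geometry.is_inhibitory, static_I, static_E)
    if dw is not None:
        if maze_neurons is None:
            raise ValueError("maze_neurons required alongside dw")
        bias[maze_neurons] += dw @ dx
    return np.abs(bias)


def bias_from_coo(post, pre, weight, geometry: LatticeGeometry) -> np.ndarray:
    """Bias measure from an explicit (post, pre, K) synapse list.

    Returns the per-source-neuron bias (indexed by presynaptic flat
    index); used as the direct-evaluation route for small networks.
    """
    post = np.asarray(post)
    pre = np.asarray(pre)
    weight = np.asarray(weight, dtype=float)
    n = geometry.n
    x_post = post // n
    x_pre = pre // n
    disp = toroidal_delta(x_pre, x_post, n).astype(float)
    out = np.zeros(geometry.n_neurons)
    np.add.at(out, pre, disp * weight)
    return np.abs(out)


def cue_asymmetry_profile(cue_synapses: CueSynapses, masks: MazeMasks,
                          cue: str) -> pd.DataFrame:
    """Mean plastic cue-synapse change per x-column, centred on the stem.

    Columns span the maze's horizontal extent; a column with no cue
    synapse is reported with NaN mean and n_synapses = 0.
    """
    n = masks.grid_size
    cx = masks.decision_point[0]
    cue_idx = list(CUE_ARM).index(cue)
    tx = cue_synapses.targets[cue_idx] // n
    dw = cue_synapses.dw[cue_idx]
    in_maze = masks.maze[cue_synapses.targets[cue_idx]]

    half = (masks.spec.width - 1) // 2
    span = half + masks.spec.arm_len
    cols = np.arange(-span, span + 1)
    mean_dw = np.full(cols.shape, np.nan)
    counts = np.zeros(cols.shape, dtype=np.int64)
    offs = tx - cx
    for i, c in enumerate(cols):
        sel = (offs == c) & in_maze
        counts[i] = int(sel.sum())
        if counts[i]:
            mean_dw[i] = float(dw[sel].mean())
    return pd.DataFrame({"column": cols, "mean_dw": mean_dw, "n_synapses": counts})


# ---------------------------------------------------------------------------
# analytic steady-state tracker for the cue-synapse weight change


def delta_w_recursion(g_sequence, A_plus: float, delta_t5: float,
                      tau_plus: float, r: float, dw0: float = 0.0) -> np.ndarray:
    """Raw per-trial recursion dW_n = A+ g_n exp(-dt5/tau+) + r dW_{n-1}.

    One STDP potentiation event per congruent trial (probability g_n) plus
    the per-trial scaling decay factor ``r``.
    """
    if not (0.0 < r < 1.0):
        raise ValueError("per-trial decay r must lie in (0, 1) for convergence")
    gain = A_plus * np.exp(-delta_t5 / tau_plus)
    g = np.asarray(g_sequence, dtype=float)
    out = np.empty(g.size)
    dw = dw0
    for i, gi in enumerate(g):
        dw = gain * gi + r * dw
        out[i] = dw
    return out


def delta_w_ss_tracker(g_sequence, A_plus: float, delta_t5: float,
                       tau_plus: float, r: float, N: int = 50):
    """Trailing-mean association and closed-form steady-state weight change.

    Returns ``(g_bar, dw_ss)`` where ``g_bar[n]`` is the mean of the
    previous ``N`` association values (all available history for early
    trials) and ``dw_ss = F * g_bar`` with
    ``F = A+ exp(-dt5/tau+) / (1 - r)`` — the fixed point of
    :func:`delta_w_recursion` at constant g.
    """
    if not (0.0 < r < 1.0):
        raise ValueError("per-trial decay r must lie in (0, 1) for convergence")
    if N < 1:
        raise ValueError("window N must be >= 1")
    g = np.asarray(g_sequence, dtype=float)
    F = A_plus * np.exp(-delta_t5 / tau_plus) / (1.0 - r)
    g_bar = np.empty(g.size)
    for i in range(g.size):
        lo = max(0, i - N)
        g_bar[i] = g[lo:i].mean() if i > 0 else g[0]
    return g_bar, F * g_bar


# ---------------------------------------------------------------------------
# estimator calibration and error CDF


@dataclass
class CalibrationResult:
    """Least-squares linear map ghat' = a*ghat + b and calibrated errors."""

    a: float
    b: float
    abs_errors: np.ndarray   # sorted |g - ghat'|

    def cdf(self, x) -> np.ndarray | float:
        """Empirical CDF of the absolute calibrated error at ``x``."""
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self.abs_errors, x, side="right") / len(self.abs_errors)
        return out if out.ndim else float(out)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.abs_errors, q))


def calibrate_and_error_cdf(estimates, truth) -> CalibrationResult:
    """Fit the linear calibration by OLS and return the error distribution.

    ``a`` and ``b`` minimize the mean squared difference between
    ``a*ghat + b`` and the true ``g`` series; the returned errors are the
    absolute calibrated residuals, sorted for CDF evaluation.  A
    zero-variance estimate series makes the fit singular and raises.
    """
    ghat = np.asarray(estimates, dtype=float)
    g = np.asarray(truth, dtype=float)
    if ghat.shape != g.shape or ghat.size < 2:
        raise ValueError("estimates and truth must be equal-length series of size >= 2")
    var = ghat.var()
    if var == 0.0:
        raise np.linalg.LinAlgError("singular calibration fit: estimates have zero variance")
    a = float(np.cov(ghat, g, ddof=0)[0, 1] / var)
    b = float(g.mean() - a * ghat.mean())
    errors = np.sort(np.abs(g - (a * ghat + b)))
    return CalibrationResult(a=a, b=b, abs_errors=errors)
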