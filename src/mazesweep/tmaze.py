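"""T-maze environment, model-rat trajectory, cue wiring and trial scheduling.

The maze is embedded in the lattice as an 11-wide corridor: a vertical
stem from the start D to the decision point A and a horizontal corridor
forming the left and right arms.  Neurons whose place fields (their grid
positions) fall outside the maze are permanently clamped and never fire.

A trial proceeds as follows.  The model rat moves at constant speed from
D toward A while a localized excitatory drive centred on it activates the
surrounding place-field bump.  On *training* trials one arm is blocked
(its neurons are voltage-clamped) and the rat continues down the goal
arm, so the evoked sequence is forced along one path; both plasticity
rules are enabled.  On *test* trials neither arm is blocked, the rat
halts at A, plasticity is frozen, and the internally generated sequence
launched by the cue is classified.  The cue neuron fires regularly during
a window around the rat's arrival at A and reaches the grid through
N = 40,000 plastic synapses wired at random (with replacement), with
initial weights matching the efferent-weight distribution of an in-grid
excitatory neuron.

Cue-goal association regimes for the goal-arm draw: constant g, a step
switch (g = 0 for the first block, then 1), and a clipped Gaussian random
walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, MazeSpec, TaskConfig
from .lattice import LatticeGeometry

__all__ = [
    "MazeMasks",
    "build_maze",
    "rat_position",
    "rat_drive",
    "CueSynapses",
    "wire_cues",
    "cue_spike_times",
    "TrialRecord",
    "schedule_trials",
    "generate_g_sequence",
]

CUES = ("C1", "C2")
#: nominal cue-goal association: C1 -> left arm, C2 -> right arm
CUE_ARM = {"C1": "L", "C2": "R"}


@dataclass
class MazeMasks:
    """Boolean membership per neuron (flat row-major index) plus landmarks."""

    spec: MazeSpec
    grid_size: int
    maze: np.ndarray
    stem: np.ndarray
    left_arm: np.ndarray
    right_arm: np.ndarray
    goal_left: np.ndarray
    goal_right: np.ndarray
    cue_zone: np.ndarray
    start: tuple          # D
    decision_point: tuple  # A

    @property
    def non_maze(self) -> np.ndarray:
        """Permanently clamped neurons (place field outside the maze)."""
        return ~self.maze

    def arm_mask(self, arm: str) -> np.ndarray:
        return self.left_arm if arm == "L" else self.right_arm

    def goal_mask(self, arm: str) -> np.ndarray:
        return self.goal_left if arm == "L" else self.goal_right

    def label_grid(self) -> np.ndarray:
        """Integer-label grid for inspection: 0 outside, 1 stem, 2/3 arms, 4/5 goals, 6 cue zone."""
        n = self.grid_size
        lab = np.zeros(n * n, dtype=np.int64)
        lab[self.stem] = 1
        lab[self.left_arm] = 2
        lab[self.right_arm] = 3
        lab[self.goal_left] = 4
        lab[self.goal_right] = 5
        lab[self.cue_zone] = 6
        return lab.reshape(n, n)


def build_maze(geometry: LatticeGeometry, spec: MazeSpec) -> MazeMasks:
    """Embed the T-maze in the lattice, centred on the grid.

    Raises :class:`ConfigurationError` if the maze (plus a margin of the
    coupling cutoff D, so the two goal zones cannot interact through the
    periodic boundary) does not fit.
    """
    n = geometry.n
    D = geometry.config.coupling_cutoff
    half = (spec.width - 1) // 2

    horiz_extent = 2 * (half + spec.arm_len) + 1
    vert_extent = spec.stem_len + spec.width
    if horiz_extent + D > n or vert_extent + D > n:
        raise ConfigurationError(
            f"maze ({horiz_extent} x {vert_extent}) plus margin D={D} exceeds grid {n}"
        )

    cx = n // 2
    y_A = min(n - half - 1, n // 2 + spec.stem_len // 2)
    y_D = y_A - spec.stem_len

    xs, ys = np.divmod(np.arange(n * n), n)

    corridor = (np.abs(ys - y_A) <= half) & (np.abs(xs - cx) <= half + spec.arm_len)
    stem = (np.abs(xs - cx) <= half) & (ys >= y_D) & (ys <= y_A + half)
    left_arm = corridor & (xs < cx - half)
    right_arm = corridor & (xs > cx + half)
    x_left_end = cx - half - spec.arm_len
    x_right_end = cx + half + spec.arm_len
    goal_left = left_arm & (xs <= x_left_end + spec.goal_zone_len - 1)
    goal_right = right_arm & (xs >= x_right_end - spec.goal_zone_len + 1)
    cue_zone = stem & (ys >= y_A - spec.cue_zone_len) & (ys < y_A)

    return MazeMasks(
        spec=spec,
        grid_size=n,
        maze=corridor | stem,
        stem=stem,
        left_arm=left_arm,
        right_arm=right_arm,
        goal_left=goal_left,
        goal_right=goal_right,
        cue_zone=cue_zone,
        start=(cx, y_D),
        decision_point=(cx, y_A),
    )


def rat_position(masks: MazeMasks, kind: str, goal_arm: str | None,
                 t: float, task: TaskConfig) -> tuple:
    """Rat position at time ``t`` (ms from trial start).

    Training: D -> A -> down the goal arm to its end.  Test: D -> A, then
    hold at the decision point.
    """
    cx, y_A = masks.decision_point
    _, y_D = masks.start
    v = task.rat_speed
    t_A = (y_A - y_D) / v
    if t <= t_A:
        return (float(cx), float(y_D + v * t))
    if kind == "test":
        return (float(cx), float(y_A))
    half = (masks.spec.width - 1) // 2
    arm_travel = half + masks.spec.arm_len
    s = min(v * (t - t_A), float(arm_travel))
    return (float(cx - s) if goal_arm == "L" else float(cx + s), float(y_A))


def trip_duration(masks: MazeMasks, task: TaskConfig) -> float:
    """Time (ms) for a full training traversal D -> A -> arm end."""
    half = (masks.spec.width - 1) // 2
    return (masks.spec.stem_len + half + masks.spec.arm_len) / task.rat_speed


def rat_drive(masks: MazeMasks, kind: str, goal_arm: str | None,
              t: float, task: TaskConfig):
    """(position, per-neuron excitatory drive, clamp mask) at time ``t``.

    The drive is a Gaussian-profile conductance injection
    ``amp * exp(-d^2 / sigma^2)`` to maze neurons within the place-field
    radius of the rat, zero beyond it and zero outside the maze.  On
    training trials the non-goal arm is clamped for the whole trial.
    """
    n = masks.grid_size
    pos = rat_position(masks, kind, goal_arm, t, task)
    xs, ys = np.divmod(np.arange(n * n), n)
    d2 = (xs - pos[0]) ** 2 + (ys - pos[1]) ** 2
    drive = task.drive_amp * np.exp(-d2 / task.drive_sigma ** 2)
    drive[d2 > task.place_field_radius ** 2] = 0.0
    drive[~masks.maze] = 0.0
    clamp = ~masks.maze
    if kind == "train":
        blocked = "L" if goal_arm == "R" else "R"
        clamp = clamp | masks.arm_mask(blocked)
    drive[clamp] = 0.0
    return pos, drive, clamp


# ---------------------------------------------------------------------------
# cue neurons


@dataclass
class CueSynapses:
    """Random plastic projections from the two cue neurons into the grid.

    ``targets[c]`` holds the flat postsynaptic index of each of the
    ``n_syn`` synapses of cue ``c`` (drawn with replacement), ``w0`` the
    static weights and ``dw`` the plastic changes.  Cue synapses follow
    STDP and scaling but are exempt from the hard limit.
    """

    targets: np.ndarray   # (2, n_syn) int64
    w0: np.ndarray        # (2, n_syn) float64
    dw: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.dw is None:
            self.dw = np.zeros_like(self.w0)

    @property
    def n_synapses(self) -> int:
        return self.targets.shape[1]

    def column_profile(self, masks: MazeMasks, cue: str) -> pd.DataFrame:
        """Mean cue dW per x-column, x centred on the stem (see sequences)."""
        from .sequences import cue_asymmetry_profile
        return cue_asymmetry_profile(self, masks, cue)


def wire_cues(geometry: LatticeGeometry, task: TaskConfig, rng) -> CueSynapses:
    """Draw the cue wiring for one network realization.

    Postsynaptic targets are uniform over the grid with replacement; the
    initial weights are sampled from the efferent-weight population of an
    in-grid excitatory neuron (one of the 1960 stencil values, uniformly),
    so the two distributions match by construction.
    """
    rng = np.random.default_rng(rng)
    n_syn = task.n_cue_synapses
    targets = rng.integers(0, geometry.n_neurons, size=(2, n_syn))
    offset_draw = rng.integers(0, geometry.n_offsets, size=(2, n_syn))
    w0 = geometry.w_pre_E[offset_draw]
    return CueSynapses(targets=targets, w0=w0)


def cue_spike_times(t_on: float, t_off: float, task: TaskConfig) -> np.ndarray:
    """Regular cue-neuron spike times (ms) at ``cue_rate`` during the window."""
    period = 1000.0 / task.cue_rate
    return np.arange(t_on, t_off, period)


def cue_window(masks: MazeMasks, task: TaskConfig, kind: str = "test") -> tuple:
    """(t_on, t_off) of the cue tone: it plays while the rat is near A.

    The window opens when the rat enters the cue zone.  On training trials
    the rat crosses the junction and the cue stops ``cue_post_ms`` after
    arrival at A; on test trials the rat stays parked at the decision
    point, so the cue keeps sounding through the observation window.
    """
    _, y_D = masks.start
    _, y_A = masks.decision_point
    t_A = (y_A - y_D) / task.rat_speed
    t_on = t_A - masks.spec.cue_zone_len / task.rat_speed
    post = task.cue_post_ms if kind == "train" else task.test_hold_ms
    return t_on, t_A + post


# ---------------------------------------------------------------------------
# trial scheduling


@dataclass
class TrialRecord:
    index: int
    kind: str            # "train" | "test"
    cue: str             # "C1" | "C2"
    goal_arm: str | None  # training goal arm; None on test trials
    plasticity: bool
    blocked_arm: str | None
    g: float
    congruent: int | None  # y_n for training trials


def schedule_trials(n_train: int, g_sequence, rng, test_cue: str = "C2",
                    observations=None) -> list:
    """Build the alternating train/test schedule.

    Training trials alternate cues C1, C2, C1, ...; on training trial n
    the goal lands on the cue-congruent arm with probability ``g_n``
    (drawn Bernoulli unless ``observations`` supplies the congruency
    indicators explicitly), and the other arm is blocked.  Every training
    trial is followed by a test trial with ``test_cue``, no blocking and
    plasticity disabled.
    """
    g = np.asarray(g_sequence, dtype=float)
    if len(g) < n_train:
        raise ValueError("g_sequence shorter than n_train")
    if np.any((g < 0) | (g > 1)):
        raise ValueError("g values must lie in [0, 1]")
    if test_cue not in CUES:
        raise ValueError(f"unknown cue {test_cue!r}")
    rng = np.random.default_rng(rng)
    if observations is None:
        observations = (rng.random(n_train) < g[:n_train]).astype(np.int64)
    else:
        observations = np.asarray(observations, dtype=np.int64)
        if len(observations) < n_train:
            raise ValueError("observations shorter than n_train")

    plan = []
    for i in range(n_train):
        cue = CUES[i % 2]
        y = int(observations[i])
        congruent_arm = CUE_ARM[cue]
        goal = congruent_arm if y else ("R" if congruent_arm == "L" else "L")
        blocked = "R" if goal == "L" else "L"
        plan.append(TrialRecord(index=i + 1, kind="train", cue=cue, goal_arm=goal,
                                plasticity=True, blocked_arm=blocked,
                                g=float(g[i]), congruent=y))
        plan.append(TrialRecord(index=i + 1, kind="test", cue=test_cue, goal_arm=None,
                                plasticity=False, blocked_arm=None,
                                g=float(g[i]), congruent=None))
    return plan


def plan_to_dataframe(plan) -> pd.DataFrame:
    return pd.DataFrame([vars(rec) for rec in plan])


def generate_g_sequence(protocol: str, n: int, rng=None, g0: float = 0.5,
                        n_switch: int = 100, Q: float = 2e-5) -> np.ndarray:
    """Cue-goal association sequence g_1..g_n for the three regimes.

    ``constant``: g_n = g0.  ``step_switch``: 0 for n <= n_switch, then 1.
    ``gaussian_walk``: g_{n+1} = clip(g_n + xi, 0, 1) with
    xi ~ Normal(0, Q) (variance Q, default 2e-5) and g_1 = g0 = 1/2; the
    clip keeps the sequence a valid probability.
    """
    if protocol == "constant":
        return np.full(n, float(g0))
    if protocol == "step_switch":
        idx = np.arange(1, n + 1)
        return np.where(idx <= n_switch, 0.0, 1.0)
    if protocol == "gaussian_walk":
        if Q < 0:
            raise ConfigurationError("random-walk variance Q must be >= 0")
        rng = np.random.default_rng(rng)
        steps = rng.normal(0.0, np.sqrt(Q), size=n - 1) if n > 1 else np.empty(0)
        g = np.empty(n)
        g[0] = g0
        for i in range(1, n):
            g[i] = min(1.0, max(0.0, g[i - 1] + steps[i - 1]))
        return g
    raise ConfigurationError(f"unknown g-sequence protocol {protocol!r}")
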