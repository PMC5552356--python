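"""End-to-end experiment orchestration: presets, seeding, serialization.

An :class:`ExperimentSpec` names one of the study protocols and its scale:

* ``learning_curve`` — deterministic cue-goal association (g = 1),
  alternating training cues, C2 test trials; produces the correct-rate
  learning curve with SEM across realizations.
* ``ablation_no_scaling`` — same with synaptic scaling disabled; late
  training is dominated by split sequences.
* ``switch`` — association reversal (g = 0 for the first block, then 1);
  circuit plus the Bayesian baselines on the same observation streams.
* ``random_walk`` — g follows a clipped Gaussian random walk
  (variance 2e-5 per trial); estimator comparison (Kalman, discounted
  Bayes, optionally the circuit) with linear calibration and error CDFs.
* ``weight_analysis`` — trains the circuit and reports the connection-bias
  measure, the cue-weight asymmetry profile and the analytic steady-state
  tracker.

Every stochastic component draws from a child of the master seed via
``numpy.random.SeedSequence(master).spawn``; realization r uses child r.
Re-running a spec therefore reproduces all outputs bit-for-bit for a
fixed dt and realization count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import ConfigurationError, MazeSpec, NetworkConfig, PlasticityConfig, TaskConfig
from .engine import CircuitSimulator
from .inference import (discounted_bayes, kalman_filter, simple_bayes,
                        simulate_cue_goal_trials)
from .sequences import (calibrate_and_error_cdf, bias_measure, correct_rate_curve,
                        cue_asymmetry_profile, delta_w_ss_tracker)
from .tmaze import generate_g_sequence, plan_to_dataframe, schedule_trials

EXPERIMENTS = ("learning_curve", "ablation_no_scaling", "switch",
               "random_walk", "weight_analysis")

#: full-size grid; scaled presets shrink grid and maze together
FULL_GRID = 200


@dataclass
class ExperimentSpec:
    """Declarative description of one experiment run."""

    experiment: str
    scale: float = 1.0
    realizations: int = 20
    n_train: int = 100
    seed: int = 0
    test_cue: str = "C2"
    # protocol parameters
    g0: float = 0.5
    n_switch: int = 100
    walk_Q: float = 2e-5
    alpha_disc: float = 0.99
    kalman_Q: float = 0.16
    kalman_Z: float = 2e-5
    include_circuit: bool = True
    enable_scaling: bool = True
    reverse_order: bool = False     # switch protocol: run 100 R then 100 L
    save_spikes: bool = False
    config_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigurationError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        if self.experiment == "ablation_no_scaling":
            self.enable_scaling = False
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")
        if self.realizations < 1 or self.n_train < 1:
            raise ConfigurationError("realizations and n_train must be >= 1")

    # -- derived configurations ------------------------------------------

    def network_config(self) -> NetworkConfig:
        """Network scaled as a physical model: all spatial ranges shrink
        with the maze (coupling cutoff and footprints included), so the
        geometric separation between the decision point and the goal
        zones is preserved; the gain auto-normalization keeps the working
        point fixed."""
        grid = int(round(FULL_GRID * self.scale))
        grid += grid % 2
        kw = dict(self.config_overrides.get("network", {}))
        kw.setdefault("grid_size", grid)
        kw.setdefault("coupling_cutoff", 25.0 * self.scale)
        kw.setdefault("d_E", 20.0 * self.scale)
        kw.setdefault("d_I", 90.0 * self.scale)
        return NetworkConfig(**kw)

    def plasticity_config(self) -> PlasticityConfig:
        kw = dict(self.config_overrides.get("plasticity", {}))
        kw.setdefault("enable_scaling", self.enable_scaling)
        return PlasticityConfig(**kw)

    def maze_spec(self) -> MazeSpec:
        kw = self.config_overrides.get("maze")
        if kw:
            return MazeSpec(**kw)
        return MazeSpec.scaled(self.scale)

    def task_config(self) -> TaskConfig:
        kw = dict(self.config_overrides.get("task", {}))
        kw.setdefault("place_field_radius", 25.0 * self.scale)
        kw.setdefault("drive_sigma", 12.5 * self.scale)
        return TaskConfig(**kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    tables: dict            # name -> DataFrame
    arrays: dict            # name -> ndarray (weight snapshots, rasters)
    summary: dict           # scalar headline numbers

    def manifest(self) -> dict:
        return {
            "experiment": self.spec.experiment,
            "spec": self.spec.to_dict(),
            "spec_hash": self.spec.content_hash(),
            "master_seed": self.spec.seed,
            "package_version": _version,
            "tables": sorted(self.tables),
            "arrays": sorted(self.arrays),
            "summary": self.summary,
        }


def _child_seeds(master: int, count: int):
    return np.random.SeedSequence(master).spawn(count)


def build_simulator(spec: ExperimentSpec, realization: int = 0) -> CircuitSimulator:
    """Construct the simulator for one realization of ``spec``."""
    child = _child_seeds(spec.seed, spec.realizations)[realization]
    return _build_simulator(spec, child)


def _build_simulator(spec: ExperimentSpec, child_seed) -> CircuitSimulator:
    rng = np.random.default_rng(child_seed)
    return CircuitSimulator(network=spec.network_config(),
                            plasticity=spec.plasticity_config(),
                            maze=spec.maze_spec(),
                            task=spec.task_config(),
                            seed=rng.integers(2 ** 31))


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Execute all realizations of ``spec`` and aggregate the results.

    Realizations are independent (one child seed each), so results do not
    depend on execution order.
    """
    runner = {
        "learning_curve": _run_learning_curve,
        "ablation_no_scaling": _run_learning_curve,
        "switch": _run_switch,
        "random_walk": _run_random_walk,
        "weight_analysis": _run_weight_analysis,
    }[spec.experiment]
    return runner(spec)


def _run_circuit_outcomes(spec: ExperimentSpec, g_seq, observations=None):
    """Run every realization over a schedule; returns outcomes + tables."""
    children = _child_seeds(spec.seed, spec.realizations)
    all_outcomes = []
    rows = []
    sims = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        sim = _build_simulator(spec, child)
        plan = schedule_trials(spec.n_train, g_seq, rng, test_cue=spec.test_cue,
                               observations=observations)
        outcomes = sim.run_plan(plan)
        all_outcomes.append(outcomes)
        sims.append(sim)
        for rec, out in zip((p for p in plan if p.kind == "test"), outcomes):
            rows.append({"realization": r, "trial": rec.index, "kind": "test",
                         "cue": rec.cue, "g": rec.g, "outcome": out.outcome,
                         "n_spikes_assoc": out.n_spikes_assoc,
                         "n_spikes_other": out.n_spikes_other})
    outcome_table = pd.DataFrame(rows)
    return all_outcomes, outcome_table, sims


def _run_learning_curve(spec: ExperimentSpec) -> ExperimentResult:
    g_seq = generate_g_sequence("constant", spec.n_train, g0=1.0)
    outcomes, table, _ = _run_circuit_outcomes(spec, g_seq)
    curve = correct_rate_curve(outcomes)
    split_frac = float((table["outcome"] == "split").mean())
    late = curve["rate"].tail(max(5, spec.n_train // 5))
    return ExperimentResult(
        spec=spec,
        tables={"learning_curve": curve, "outcomes": table},
        arrays={},
        summary={"final_rate": float(late.mean()),
                 "split_fraction": split_frac},
    )


def _run_switch(spec: ExperimentSpec) -> ExperimentResult:
    g_seq = generate_g_sequence("step_switch", spec.n_train, n_switch=spec.n_switch)
    # deterministic observations under g in {0,1}
    observations = (g_seq > 0.5).astype(np.int64)
    if spec.reverse_order:
        observations = observations[::-1].copy()
    results = {}
    tables = {}
    if spec.include_circuit:
        outcomes, table, _ = _run_circuit_outcomes(spec, g_seq, observations)
        curve = correct_rate_curve(outcomes)
        tables["circuit_curve"] = curve
        tables["outcomes"] = table
        results["circuit_final"] = float(curve["rate"].tail(10).mean())
    simple = simple_bayes(observations)
    disc = discounted_bayes(observations, spec.alpha_disc)
    trace = pd.DataFrame({
        "trial": np.arange(1, len(observations) + 1),
        "y": observations,
        "g_true": g_seq,
        "ghat_simple": simple.estimates,
        "ghat_discounted": disc.estimates,
    })
    tables["estimator_trace"] = trace
    results["simple_final"] = float(simple.estimates[-1])
    results["discounted_final"] = float(disc.estimates[-1])
    return ExperimentResult(spec=spec, tables=tables, arrays={}, summary=results)


def _run_random_walk(spec: ExperimentSpec) -> ExperimentResult:
    root = np.random.SeedSequence(spec.seed)
    g_rng, y_rng = (np.random.default_rng(s) for s in root.spawn(2))
    g_seq = generate_g_sequence("gaussian_walk", spec.n_train, rng=g_rng,
                                g0=spec.g0, Q=spec.walk_Q)
    y = simulate_cue_goal_trials(g_seq, y_rng)
    disc = discounted_bayes(y, spec.alpha_disc)
    kal = kalman_filter(y, Q=spec.kalman_Q, Z=spec.kalman_Z, g0=spec.g0)
    trace = pd.DataFrame({
        "trial": np.arange(1, len(y) + 1),
        "y": y,
        "g_true": g_seq,
        "ghat_discounted": disc.estimates,
        "ghat_kalman": kal.estimates,
        "kalman_gain": kal.gains,
        "kalman_cov": kal.covariances,
    })
    burn = min(50, len(y) // 5)
    cal_disc = calibrate_and_error_cdf(disc.estimates[burn:], g_seq[burn:])
    cal_kal = calibrate_and_error_cdf(kal.estimates[burn:], g_seq[burn:])
    summary = {
        "kalman_median_error": cal_kal.quantile(0.5),
        "discounted_median_error": cal_disc.quantile(0.5),
        "kalman_cdf_at_0.03": cal_kal.cdf(0.03),
        "kalman_cdf_at_0.05": cal_kal.cdf(0.05),
    }
    tables = {"estimator_trace": trace}
    if spec.include_circuit:
        # circuit congruent-choice rate across realizations, trial by trial
        outcomes, table, _ = _run_circuit_outcomes(spec, g_seq)
        tables["outcomes"] = table
        congruent = (table.pivot_table(index="realization", columns="trial",
                                       values="outcome",
                                       aggfunc=lambda s: (s == "correct").mean())
                     .to_numpy())
        rate = congruent.mean(axis=0)
        tables["circuit_trace"] = pd.DataFrame({
            "trial": np.arange(1, len(rate) + 1), "congruent_rate": rate})
        cal_circ = calibrate_and_error_cdf(rate[burn:], g_seq[burn:])
        summary["circuit_median_error"] = cal_circ.quantile(0.5)
        summary["circuit_cdf_at_0.03"] = cal_circ.cdf(0.03)
        summary["circuit_cdf_at_0.05"] = cal_circ.cdf(0.05)
    return ExperimentResult(spec=spec, tables=tables, arrays={}, summary=summary)


def _run_weight_analysis(spec: ExperimentSpec) -> ExperimentResult:
    g_seq = generate_g_sequence("constant", spec.n_train, g0=1.0)
    child = _child_seeds(spec.seed, 1)[0]
    rng = np.random.default_rng(child)
    sim = _build_simulator(spec, child)
    plan = schedule_trials(spec.n_train, g_seq, rng, test_cue=spec.test_cue)
    sim.run_plan(plan)

    bias = bias_measure(sim.geometry, sim.dw_rec, sim.maze_neurons)
    profile = cue_asymmetry_profile(sim.cues, sim.masks, spec.test_cue)

    plast = sim.plasticity
    task = sim.task
    period = sim.trial_duration("train") + task.trial_gap
    r = float(np.exp(-period / plast.tau_s))
    g_bar, dw_ss = delta_w_ss_tracker(g_seq, plast.A_plus, 5.0, plast.tau_plus, r)
    tracker = pd.DataFrame({"trial": np.arange(1, len(g_seq) + 1),
                            "g_bar": g_bar, "dw_ss": dw_ss})

    n = sim.geometry.n
    xs = sim.maze_neurons // n
    cx = sim.masks.decision_point[0]
    bias_table = pd.DataFrame({
        "neuron": sim.maze_neurons,
        "column": xs - cx,
        "stem": sim.masks.stem[sim.maze_neurons],
        "bias": bias[sim.maze_neurons],
    })
    stem_bias = float(bias_table.loc[bias_table["stem"], "bias"].mean())
    arm_bias = float(bias_table.loc[~bias_table["stem"], "bias"].mean())
    return ExperimentResult(
        spec=spec,
        tables={"bias": bias_table, "cue_profile": profile, "dw_ss": tracker,
                "trial_plan": plan_to_dataframe(plan)},
        arrays={"dw_rec": sim.dw_rec.copy(),
                "cue_dw": sim.cues.dw.copy(),
                "cue_w0": sim.cues.w0.copy(),
                "cue_targets": sim.cues.targets.copy()},
        summary={"stem_mean_bias": stem_bias, "arm_mean_bias": arm_bias},
    )


# ---------------------------------------------------------------------------
# serialization


def write_outputs(result: ExperimentResult, outdir: str | Path) -> Path:
    """Write tables as CSV, arrays as HDF5 and the manifest as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in result.tables.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
    if result.arrays:
        with h5py.File(outdir / "arrays.h5", "w") as fh:
            for name, arr in result.arrays.items():
                fh.create_dataset(name, data=arr, compression="gzip")
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest(), indent=2, sort_keys=True, default=float))
    return outdir


def read_outputs(outdir: str | Path) -> ExperimentResult:
    """Round-trip loader for :func:`write_outputs` bundles."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    tables = {p.stem: pd.read_csv(p) for p in sorted(outdir.glob("*.csv"))}
    arrays = {}
    h5 = outdir / "arrays.h5"
    if h5.exists():
        with h5py.File(h5, "r") as fh:
            arrays = {name: fh[name][...] for name in fh}
    spec = ExperimentSpec(**manifest["spec"])
    return ExperimentResult(spec=spec, tables=tables, arrays=arrays,
                            summary=manifest["summary"])
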