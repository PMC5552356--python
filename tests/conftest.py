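import numpy as np
import pytest
from hypothesis import settings

import mazesweep as mz

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> mz.NetworkConfig:
    return mz.NetworkConfig()


@pytest.fixture(scope="session")
def default_geometry(default_config) -> mz.LatticeGeometry:
    return mz.build_geometry(default_config)


@pytest.fixture(scope="session")
def tiny_config() -> mz.NetworkConfig:
    """A 20x20 lattice with a short-range kernel; cheap enough for
    explicit sparse enumeration."""
    return mz.NetworkConfig(grid_size=20, coupling_cutoff=6.25, d_E=5.0, d_I=22.5)


@pytest.fixture(scope="session")
def tiny_geometry(tiny_config) -> mz.LatticeGeometry:
    return mz.build_geometry(tiny_config)


def quarter_scale_spec(**kw) -> mz.ExperimentSpec:
    """Quarter-scale circuit spec: fast enough for functional smoke tests."""
    kw.setdefault("experiment", "learning_curve")
    kw.setdefault("scale", 0.25)
    kw.setdefault("realizations", 2)
    kw.setdefault("n_train", 6)
    kw.setdefault("seed", 0)
    return mz.ExperimentSpec(**kw)


@pytest.fixture(scope="session")
def trained_half_scale_sim():
    """One half-scale realization trained for 40 trials under g = 1.

    Session-scoped because several analyses (outcomes, cue asymmetry,
    bias, blocking/containment invariants) read from the same trained
    network.
    """
    spec = mz.ExperimentSpec(experiment="learning_curve", scale=0.5,
                             realizations=1, n_train=40, seed=0)
    sim = mz.build_simulator(spec)
    rng = np.random.default_rng(123)
    plan = mz.schedule_trials(spec.n_train, np.ones(spec.n_train), rng)
    records = []
    outcomes = []
    for rec in plan:
        spikes = sim.run_trial(rec)
        records.append((rec, spikes))
        if rec.kind == "test":
            outcomes.append(sim.classify(spikes))
    return {"sim": sim, "plan": plan, "records": records, "outcomes": outcomes}
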