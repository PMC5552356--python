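"""Configuration objects for the spiking lattice, plasticity rules and T-maze task.

All defaults reproduce the published model: a 200 x 200 toroidal grid of
conductance-based integrate-and-fire neurons (inhibitory where both
coordinates are even), Gaussian distance-dependent coupling cut off at
``coupling_cutoff`` grid units, pair-based STDP with exponential windows,
and slow homeostatic synaptic scaling that relaxes weight changes back to
baseline.

Configurations are plain dataclasses that validate themselves on
construction and round-trip through YAML (:func:`load_config`,
:func:`save_config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml

__all__ = [
    "ConfigurationError",
    "NetworkConfig",
    "PlasticityConfig",
    "MazeSpec",
    "TaskConfig",
    "load_config",
    "save_config",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates a structural invariant."""


@dataclass
class NetworkConfig:
    """Parameters of the 2D lattice and single-neuron dynamics.

    Membrane quantities are in the units conventional for conductance-based
    point neurons: capacitance in uF/cm^2, conductances in uS/cm^2,
    potentials in mV, times in ms.  Coupling weights (``C_E``, ``C_I``) are
    in model weight units; ``conductance_gain`` converts accumulated
    weight * kernel input into uS/cm^2 (the published parameter set leaves
    this overall scale free).
    """

    grid_size: int = 200
    coupling_cutoff: float = 25.0       # D, grid units
    d_E: float = 20.0                   # excitatory footprint width
    d_I: float = 90.0                   # inhibitory footprint width
    C_E: float = 5e-7                   # excitatory weight scale
    C_I: float = 2.4e-7                 # inhibitory weight scale
    C_m: float = 1.0                    # uF/cm^2
    g_L: float = 50.0                   # uS/cm^2
    V_L: float = -70.0
    V_E: float = 0.0
    V_I: float = -80.0
    V_th: float = -55.0
    V_R: float = -70.0
    tau_ref: float = 5.0                # ms
    tau_d: float = 2.0                  # synaptic decay, ms (both classes)
    tau_r: float = 0.5                  # synaptic rise, ms (both classes)
    F_E: float = 0.0                    # tonic excitatory conductance
    F_I: float = 15.0                   # tonic inhibitory conductance
    dt: float = 0.1                     # integration step, ms
    # Conversion from weight units to uS/cm^2.  By default the gain is
    # normalized so that the summed static excitatory afferent weight of a
    # neuron maps to ``exc_input_scale`` uS/cm^2, which makes the working
    # point independent of the coupling footprint; calibrated once so a
    # driven place-field bump fires while the quiescent network is silent
    # and a trained (but uncued) network does not launch arm sequences.
    exc_input_scale: float = 1220.0
    conductance_gain: float | None = None  # explicit override of the gain

    def __post_init__(self) -> None:
        if self.grid_size <= 0 or self.grid_size % 2 != 0:
            raise ConfigurationError(
                f"grid_size must be a positive even integer, got {self.grid_size}"
            )
        if not (0 < self.coupling_cutoff < self.grid_size / 2):
            raise ConfigurationError(
                "coupling_cutoff must satisfy 0 < D < grid_size/2 "
                f"(got D={self.coupling_cutoff}, grid={self.grid_size})"
            )
        if not (0 < self.tau_r < self.tau_d):
            raise ConfigurationError("require 0 < tau_r < tau_d")
        if not (self.V_I < self.V_th < self.V_E):
            raise ConfigurationError("require V_I < V_th < V_E")
        for name in ("tau_ref", "dt", "C_m", "g_L"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def n_neurons(self) -> int:
        return self.grid_size * self.grid_size

    @property
    def membrane_tau(self) -> float:
        """Leak membrane time constant in ms (1000 * C_m / g_L)."""
        return 1000.0 * self.C_m / self.g_L


@dataclass
class PlasticityConfig:
    """STDP window, pairing cutoff, synaptic scaling and the hard limit.

    ``A_plus``/``A_minus`` are in the same weight units as the static
    coupling scales.  Scaling multiplies every plastic weight change by
    ``1 - scaling_interval*dt/tau_s`` once per ``scaling_interval``
    integration steps, i.e. exponential relaxation toward the static
    baseline with timescale ``tau_s``.
    """

    A_plus: float = 1.2e-9
    A_minus: float = 1.2e-9
    tau_plus: float = 20.0              # ms
    tau_minus: float = 20.0             # ms
    pair_cutoff: float = 100.0          # ms; 5 * tau
    tau_s: float = 7000.0               # scaling timescale, ms
    scaling_interval: int = 100         # integration steps between scalings
    limit_factor: float = 0.12          # L: |dW| <= L * |W0| (recurrent only)
    enable_stdp: bool = True
    enable_scaling: bool = True

    def __post_init__(self) -> None:
        if self.A_plus < 0 or self.A_minus < 0:
            raise ConfigurationError("A_plus/A_minus must be >= 0")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ConfigurationError("STDP time constants must be positive")
        if self.tau_s <= 0:
            raise ConfigurationError("tau_s must be positive")
        if self.limit_factor <= 0:
            raise ConfigurationError("limit_factor must be positive")
        if self.scaling_interval <= 0:
            raise ConfigurationError("scaling_interval must be positive")

    def scaling_factor(self, dt: float) -> float:
        """Multiplicative factor (1 + C_s) applied every scaling interval."""
        c_s = -(self.scaling_interval * dt) / self.tau_s
        if abs(c_s) >= 1.0:
            raise ConfigurationError(
                "scaling step too coarse: |C_s| >= 1 "
                f"(interval={self.scaling_interval}, dt={dt}, tau_s={self.tau_s})"
            )
        return 1.0 + c_s


@dataclass
class MazeSpec:
    """Geometry of the T-maze embedded in the lattice (grid units).

    The maze is an 11-wide corridor: a vertical stem of length ``stem_len``
    from the start D up to the decision point A, and a horizontal corridor
    of two arms of length ``arm_len`` each.  Goal zones are the terminal
    ``goal_zone_len`` columns of each arm; the cue zone is the last
    ``cue_zone_len`` rows of the stem below A.
    """

    width: int = 11
    stem_len: int = 60
    arm_len: int = 40
    goal_zone_len: int = 10
    cue_zone_len: int = 20

    def __post_init__(self) -> None:
        if self.width <= 0 or self.width % 2 == 0:
            raise ConfigurationError("maze width must be a positive odd integer")
        if self.stem_len <= 0 or self.arm_len <= 0:
            raise ConfigurationError("stem/arm lengths must be positive")
        if self.goal_zone_len > self.arm_len:
            raise ConfigurationError("goal zone longer than arm")
        if self.cue_zone_len > self.stem_len:
            raise ConfigurationError("cue zone longer than stem")

    @classmethod
    def scaled(cls, scale: float, width: int = 11) -> "MazeSpec":
        """Half- or double-size maze (corridor width is kept at 11)."""
        return cls(
            width=width,
            stem_len=max(4, round(60 * scale)),
            arm_len=max(4, round(40 * scale)),
            goal_zone_len=max(2, round(10 * scale)),
            cue_zone_len=max(2, round(20 * scale)),
        )


@dataclass
class TaskConfig:
    """Model-rat trajectory, drive, cue activation and trial timing.

    The rat moves at ``rat_speed`` grid units per ms, so the default
    full-size maze (stem 60 + arm 40) is traversed in ~100 ms; trials are
    separated by ``trial_gap`` = 150 ms.  The drive is a Gaussian-profile
    excitatory conductance injection centred on the rat, truncated at the
    place-field radius (25 grid units, matching the excitatory coupling
    range).
    """

    rat_speed: float = 1.0              # grid units / ms
    place_field_radius: float = 25.0    # drive cutoff, grid units
    drive_amp: float = 50.0             # uS/cm^2 at the rat's position
    drive_sigma: float = 12.5           # Gaussian half-width of the drive
    hold_drive_factor: float = 1.0      # drive attenuation while paused at A
    trial_gap: float = 150.0            # ms between trials
    cue_rate: float = 400.0             # cue neuron firing rate, Hz
    cue_post_ms: float = 10.0           # cue off this long after A (training)
    test_hold_ms: float = 100.0         # observation window on test trials
    spike_threshold: int = 5            # goal-zone spikes needed for a choice
    n_cue_synapses: int = 40000         # per cue neuron (full-scale default)

    def __post_init__(self) -> None:
        if self.rat_speed <= 0:
            raise ConfigurationError("rat_speed must be positive")
        if self.place_field_radius <= 0:
            raise ConfigurationError("place_field_radius must be positive")
        if self.n_cue_synapses <= 0:
            raise ConfigurationError("n_cue_synapses must be positive")


_SECTIONS = {
    "network": NetworkConfig,
    "plasticity": PlasticityConfig,
    "maze": MazeSpec,
    "task": TaskConfig,
}


def save_config(path: str | Path, **sections) -> None:
    """Write configuration dataclasses to a YAML file keyed by section."""
    payload = {}
    for key, obj in sections.items():
        if key not in _SECTIONS:
            raise ConfigurationError(f"unknown configuration section {key!r}")
        payload[key] = asdict(obj)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file into dataclass instances.

    Unknown sections or fields raise :class:`ConfigurationError` with the
    offending path, so typos in experiment specs fail loudly.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for key, values in raw.items():
        cls = _SECTIONS.get(key)
        if cls is None:
            raise ConfigurationError(f"unknown configuration section {key!r}")
        valid = {f.name for f in fields(cls)}
        bad = set(values) - valid
        if bad:
            raise ConfigurationError(f"unknown field(s) {sorted(bad)} in section {key!r}")
        out[key] = cls(**values)
    return out
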