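"""Event records produced by the simulation engine."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SpikeRecord:
    """Spike events of one trial: parallel (neuron, time) arrays.

    ``neuron`` holds flat row-major grid indices; ``duration`` is the
    simulated trial length in ms (used to validate analysis windows).
    """

    neuron: np.ndarray
    t: np.ndarray
    grid_size: int
    duration: float
    trial_index: int = 0
    kind: str = "test"
    cue: str | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.neuron)

    def to_dataframe(self) -> pd.DataFrame:
        x, y = np.divmod(self.neuron, self.grid_size)
        return pd.DataFrame({
            "trial": self.trial_index,
            "neuron_id": self.neuron,
            "x": x,
            "y": y,
            "t_ms": self.t,
        })

    def in_window(self, t0: float, t1: float) -> "SpikeRecord":
        sel = (self.t >= t0) & (self.t < t1)
        return SpikeRecord(neuron=self.neuron[sel], t=self.t[sel],
                           grid_size=self.grid_size, duration=self.duration,
                           trial_index=self.trial_index, kind=self.kind,
                           cue=self.cue, meta=self.meta)
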