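"""In-memory trajectory: periodic snapshots of a simulation.

Positions are stored unwrapped (true Cartesian coordinates, reduced units)
so polymer geometry — radius of gyration, bond statistics — can be computed
without periodic-image artefacts; analyses that need wrapped coordinates
re-wrap with the stored box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Frame:
    step: int
    box_side: float
    positions: np.ndarray  # (N, 3), unwrapped, reduced units
    types: np.ndarray      # (N,), 0 = water, 1 = monomer


@dataclass
class Trajectory:
    """Ordered snapshots plus run metadata (temperature, engine, seed, rc)."""

    frames: list[Frame] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def append(self, step: int, box_side: float, positions: np.ndarray,
               types: np.ndarray) -> None:
        if self.frames:
            if len(positions) != len(self.frames[0].positions):
                raise ValueError("bead count changed between frames")
            if step < self.frames[-1].step:
                raise ValueError("non-monotone step index")
        self.frames.append(Frame(step=int(step), box_side=float(box_side),
                                 positions=np.asarray(positions, dtype=float),
                                 types=np.asarray(types)))

    def polymer_indices(self) -> np.ndarray:
        if not self.frames:
            return np.empty(0, dtype=np.int64)
        return np.flatnonzero(self.frames[0].types == 1)

    def water_indices(self) -> np.ndarray:
        if not self.frames:
            return np.empty(0, dtype=np.int64)
        return np.flatnonzero(self.frames[0].types == 0)
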