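"""Frame-wise footfall (gait) diagrams.

A footfall diagram records, for every video or simulation frame, which of the
six legs is in stance (foot on the substrate).  Legs are always ordered
``L1, R1, L2, R2, L3, R3`` (left/right front, middle, rear), matching the
column order of the on-disk CSV dialect::

    frame,L1,R1,L2,R2,L3,R3
    0,1,0,0,1,1,0
    ...

with a JSON sidecar ``{"frame_rate": ..., "source": ...}`` next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical leg order used throughout the package.
LEGS: tuple[str, ...] = ("L1", "R1", "L2", "R2", "L3", "R3")

LEG_INDEX: dict[str, int] = {leg: i for i, leg in enumerate(LEGS)}

VALID_SOURCES = ("simulated", "synthetic", "annotated")


@dataclass
class FootfallDiagram:
    """Boolean stance matrix (frames x 6 legs) at a known frame rate.

    Parameters
    ----------
    stance
        Boolean array of shape ``(n_frames, 6)``; ``True`` marks stance.
    frame_rate
        Acquisition rate in Hz (500 for fly videography, 1/dt for simulation).
    source
        One of ``{"simulated", "synthetic", "annotated"}``.
    frames_per_cycle
        Number of frames per stride cycle, when known (set by generators and
        by the simulator; estimated from R1 stance onsets otherwise).
    """

    stance: np.ndarray
    frame_rate: float
    source: str = "synthetic"
    frames_per_cycle: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.stance = np.asarray(self.stance, dtype=bool)
        if self.stance.ndim != 2 or self.stance.shape[1] != len(LEGS):
            raise ValueError("stance must have shape (n_frames, 6)")
        if self.stance.shape[0] < 1:
            raise ValueError("diagram needs at least one frame")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"source must be one of {VALID_SOURCES}")

    @property
    def n_frames(self) -> int:
        return self.stance.shape[0]

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_frames / self.frame_rate

    def leg(self, name: str) -> np.ndarray:
        """Stance trace of one leg by name."""
        return self.stance[:, LEG_INDEX[name]]

    def stance_counts(self) -> np.ndarray:
        """Number of legs in stance at every frame."""
        return self.stance.sum(axis=1)

    # ------------------------------------------------------------------ IO
    def to_csv(self, path: str | Path) -> Path:
        """Write the CSV dialect plus the JSON sidecar; returns the CSV path."""
        path = Path(path)
        df = pd.DataFrame(self.stance.astype(int), columns=list(LEGS))
        df.insert(0, "frame", np.arange(self.n_frames))
        df.to_csv(path, index=False)
        sidecar = {
            "frame_rate": self.frame_rate,
            "source": self.source,
            "frames_per_cycle": self.frames_per_cycle,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
        return path

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        frame_rate: float | None = None,
        source: str | None = None,
    ) -> "FootfallDiagram":
        """Read the CSV dialect; sidecar values can be overridden."""
        path = Path(path)
        df = pd.read_csv(path)
        missing = [leg for leg in LEGS if leg not in df.columns]
        if missing:
            raise ValueError(f"footfall CSV misses leg columns: {missing}")
        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        fr = frame_rate if frame_rate is not None else meta.get("frame_rate")
        if fr is None:
            raise ValueError("frame_rate not given and no sidecar found")
        return cls(
            stance=df[list(LEGS)].to_numpy(dtype=bool),
            frame_rate=float(fr),
            source=source or meta.get("source", "annotated"),
            frames_per_cycle=meta.get("frames_per_cycle"),
        )

    def __eq__(self, other: object) -> bool:  # noqa: D105
        if not isinstance(other, FootfallDiagram):
            return NotImplemented
        return (
            np.array_equal(self.stance, other.stance)
            and self.frame_rate == other.frame_rate
        )
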