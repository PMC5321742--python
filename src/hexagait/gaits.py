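"""Phase-vector gait representation, ideal gait classes and classification.

A hexapod gait is encoded as the relative phase of each leg's periodic motion
cycle.  The left front leg (L1) anchors the encoding at 0 degrees, so five
free phases fully determine a (straight, constant-frequency) gait.  The
classic tripod gait is ``(L1, R1, L2, R2, L3, R3) = (0, 180, 180, 0, 0, 180)``:
two alternating support triangles {L1, R2, L3} and {R1, L2, R3}.

Gait classes are compared through a per-leg circular phase error: the sum over
the six legs of the minimal angular distance between an observed phase and the
class's ideal phase.  Footfall-signature similarity resolves ambiguous cases,
because the realised footfall pattern — not the raw phase vector — is what
determines locomotor success.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .footfall import LEGS, FootfallDiagram

__all__ = [
    "GaitPhaseVector",
    "GaitClassEntry",
    "GaitClassTable",
    "wrap_phase_diff",
    "signed_phase_delta",
    "classification_error",
    "classify_gait",
    "ideal_footfall",
    "default_class_table",
]


# --------------------------------------------------------------------------
# circular phase arithmetic
# --------------------------------------------------------------------------
def wrap_phase_diff(a: float, b: float) -> float:
    """Minimal circular distance between two angles in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return float(np.minimum(d, 360.0 - d)) if np.ndim(d) == 0 else np.minimum(d, 360.0 - d)


def cycle_position(x, eps: float = 1e-9):
    """Fractional cycle position ``x mod 1`` robust to float wrap jitter.

    Values within ``eps`` below 1 are mapped to exactly 0 so that cycle
    boundaries hit by accumulated rounding error land at the cycle start.
    """
    c = np.asarray(x, dtype=float) % 1.0
    c = np.where(c > 1.0 - eps, 0.0, c)
    return float(c) if np.ndim(x) == 0 else c


def signed_phase_delta(target: np.ndarray, current: np.ndarray, period: float = 1.0) -> np.ndarray:
    """Signed shortest periodic displacement ``target - current`` per dimension.

    Works on any period (degrees use 360, normalized phases use 1).
    """
    d = (np.asarray(target, float) - np.asarray(current, float)) % period
    return np.where(d > period / 2.0, d - period, d)


# --------------------------------------------------------------------------
# gait phase vector
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class GaitPhaseVector:
    """Six leg phases in degrees, L1 fixed at 0, order (L1,R1,L2,R2,L3,R3)."""

    phases: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.phases) != 6:
            raise ValueError("exactly six leg phases required")
        wrapped = tuple(float(p) % 360.0 for p in self.phases)
        if wrapped[0] != 0.0:
            raise ValueError("phase of L1 must be 0 degrees")
        object.__setattr__(self, "phases", wrapped)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "GaitPhaseVector":
        return cls(tuple(mapping[leg] for leg in LEGS))  # type: ignore[arg-type]

    @classmethod
    def from_free(cls, free: Iterable[float]) -> "GaitPhaseVector":
        """Build from the five free phases (R1, L2, R2, L3, R3) in degrees."""
        free = tuple(float(p) for p in free)
        if len(free) != 5:
            raise ValueError("five free phases required")
        return cls((0.0,) + free)  # type: ignore[arg-type]

    @classmethod
    def from_normalized(cls, x: Iterable[float]) -> "GaitPhaseVector":
        """Build from five normalized phases in [0, 1) (the optimizer encoding)."""
        return cls.from_free([360.0 * (float(v) % 1.0) for v in x])

    @property
    def free(self) -> np.ndarray:
        """The five free phases (R1, L2, R2, L3, R3) in degrees."""
        return np.asarray(self.phases[1:], dtype=float)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.phases, dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(LEGS, self.phases))

    def __getitem__(self, leg: str) -> float:
        return self.as_dict()[leg]


#: Printed classic tripod gait.
TRIPOD_A = GaitPhaseVector((0, 180, 180, 0, 0, 180))
#: Alternative tripod: front+middle of one side with the opposite rear leg.
TRIPOD_B = GaitPhaseVector((0, 180, 0, 180, 180, 0))
#: Bipod gaits: pairs (L1,R3), (R1,L3), (L2,R2) step as three groups.
BIPOD_A = GaitPhaseVector((0, 240, 120, 120, 240, 0))
BIPOD_B = GaitPhaseVector((0, 120, 240, 240, 120, 0))


def classification_error(v: GaitPhaseVector, ideal: GaitPhaseVector) -> float:
    """Phase-vector error metric: summed per-leg minimal circular difference.

    Symmetric, non-negative, and zero iff the two vectors agree up to 360
    degree wrapping.  Units: degrees (0 .. 1080).
    """
    a, b = v.as_array(), ideal.as_array()
    d = np.abs(a - b) % 360.0
    return float(np.sum(np.minimum(d, 360.0 - d)))


# --------------------------------------------------------------------------
# idealized footfall rendering
# --------------------------------------------------------------------------
def ideal_footfall(
    v: GaitPhaseVector,
    duty: float,
    cycles: int,
    frames_per_cycle: int,
    frame_rate: float | None = None,
    source: str = "synthetic",
) -> FootfallDiagram:
    """Render the idealized gait diagram of a phase vector.

    A leg is in stance at frame ``t`` iff its fractional cycle position
    ``(t / frames_per_cycle + phase/360) mod 1`` is below ``duty``.
    """
    if not 0.0 < duty < 1.0:
        raise ValueError("duty must lie strictly between 0 and 1")
    if cycles < 1:
        raise ValueError("need at least one cycle")
    if frames_per_cycle < 4:
        raise ValueError("need at least 4 frames per cycle")
    n = cycles * frames_per_cycle
    t = np.arange(n)[:, None] / frames_per_cycle
    phase = v.as_array()[None, :] / 360.0
    c = cycle_position(t + phase)
    return FootfallDiagram(
        stance=c < duty - 1e-9,
        frame_rate=frame_rate if frame_rate is not None else float(frames_per_cycle),
        source=source,
        frames_per_cycle=frames_per_cycle,
    )


# --------------------------------------------------------------------------
# gait class table and classifier
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class GaitClassEntry:
    name: str
    vector: GaitPhaseVector
    duty: float
    provisional: bool = False

    def footfall_signature(self) -> frozenset[frozenset[int]]:
        """Set of stance-sets (leg-index sets) in the class's ideal diagram."""
        diagram = ideal_footfall(self.vector, self.duty, cycles=1, frames_per_cycle=360)
        return frozenset(
            frozenset(np.flatnonzero(row)) for row in diagram.stance
        )


@dataclass
class GaitClassTable:
    """Named ideal phase vectors used by the classifier."""

    entries: dict[str, GaitClassEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("gait class table must not be empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GaitClassTable":
        raw = yaml.safe_load(Path(path).read_text())
        entries = {}
        for name, spec in raw.items():
            entries[name] = GaitClassEntry(
                name=name,
                vector=GaitPhaseVector.from_mapping(spec["phases"]),
                duty=float(spec.get("duty", 0.5)),
                provisional=bool(spec.get("provisional", False)),
            )
        return cls(entries)

    def to_yaml(self, path: str | Path) -> Path:
        raw = {
            name: {
                "phases": e.vector.as_dict(),
                "duty": e.duty,
                "provisional": e.provisional,
            }
            for name, e in self.entries.items()
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
        return Path(path)


def default_class_table() -> GaitClassTable:
    """Six-class table: tripod-A/B/C and bipod-A/B/C.

    The C variants ship as provisional copies of their A variants (their exact
    ideal vectors are not pinned down by published data); they can be
    overridden from a YAML config.  Tripod classes use duty 0.5, bipod classes
    duty 1/3 (two respectively three power strokes per cycle).
    """
    entries = {
        "tripod-A": GaitClassEntry("tripod-A", TRIPOD_A, 0.5),
        "tripod-B": GaitClassEntry("tripod-B", TRIPOD_B, 0.5),
        "tripod-C": GaitClassEntry("tripod-C", TRIPOD_A, 0.5, provisional=True),
        "bipod-A": GaitClassEntry("bipod-A", BIPOD_A, 1 / 3),
        "bipod-B": GaitClassEntry("bipod-B", BIPOD_B, 1 / 3),
        "bipod-C": GaitClassEntry("bipod-C", BIPOD_A, 1 / 3, provisional=True),
    }
    return GaitClassTable(entries)


def _signature_similarity(
    footfall: FootfallDiagram, signature: frozenset[frozenset[int]]
) -> float:
    """Fraction of frames whose stance-set occurs in the reference signature."""
    sets = [frozenset(np.flatnonzero(row)) for row in footfall.stance]
    if not sets:
        return 0.0
    return sum(s in signature for s in sets) / len(sets)


def classify_gait(
    v: GaitPhaseVector,
    footfall: FootfallDiagram,
    table: GaitClassTable | None = None,
    ambiguity_margin: float = 30.0,
    unclear_threshold: float = 360.0,
) -> str:
    """Assign a gait to the best-matching named class, or ``"unclear"``.

    The primary criterion is the phase-vector error; when the two smallest
    errors differ by less than ``ambiguity_margin`` the tie is resolved by
    footfall-signature similarity (how often the observed stance-set occurs
    in the class's idealized diagram).  Gaits whose best error exceeds
    ``unclear_threshold`` are asymmetric/unstructured and return "unclear".
    """
    table = table or default_class_table()
    # stable order: non-provisional entries first so A-variants win exact ties
    ordered = sorted(
        table.entries.values(), key=lambda e: (e.provisional, e.name)
    )
    errors = [(classification_error(v, e.vector), e) for e in ordered]
    errors.sort(key=lambda pair: pair[0])
    best_err, best = errors[0]
    if best_err > unclear_threshold:
        return "unclear"
    if len(errors) > 1 and errors[1][0] - best_err < ambiguity_margin:
        contenders = [e for err, e in errors if err - best_err < ambiguity_margin]
        sims = [
            (_signature_similarity(footfall, e.footfall_signature()), -i, e)
            for i, e in enumerate(contenders)
        ]
        sims.sort(reverse=True)
        return sims[0][2].name
    return best.name
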