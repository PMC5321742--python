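"""Synthetic fly-like footfall data and incline (tilt-test) datasets.

High-speed videography of fast-walking flies yields boolean stance traces per
leg at 500 fps with stride frequencies around 20 Hz.  Manual annotation of
such videos is noisy: stance onsets/offsets jitter by a frame or two, and
brief spurious swing (slip) or stance blips appear.  This module renders the
ideal footfall diagram of any named gait class and perturbs it with exactly
that kind of bout-boundary noise, so every analysis-stage metric can be
exercised — and its recovery quantified — without any recording.

The tilt-table experiment (raise the substrate until the animal slides; the
slide-onset angle theta gives mu_s = tan theta) is emulated as Gaussian
angular noise around arctan of a true friction coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .footfall import FootfallDiagram
from .gaits import (
    BIPOD_A,
    BIPOD_B,
    TRIPOD_A,
    TRIPOD_B,
    GaitPhaseVector,
    ideal_footfall,
)

__all__ = [
    "NoiseModel",
    "CLASS_VECTORS",
    "CLASS_DUTY",
    "generate_fly_trial",
    "generate_incline_dataset",
    "estimate_friction_coefficient",
]

#: Metachronal wave gait (swing sweeps rear-to-front per side, sides antiphase).
WAVE = GaitPhaseVector((0, 180, 120, 300, 240, 60))
#: Tetrapod gait: diagonal pairs step as three groups of two, duty 2/3.
TETRAPOD = GaitPhaseVector((0, 240, 120, 0, 240, 120))

CLASS_VECTORS: dict[str, GaitPhaseVector] = {
    "tripod-A": TRIPOD_A,
    "tripod-B": TRIPOD_B,
    "tripod-C": TRIPOD_A,
    "bipod-A": BIPOD_A,
    "bipod-B": BIPOD_B,
    "bipod-C": BIPOD_A,
    "wave": WAVE,
    "tetrapod": TETRAPOD,
}

CLASS_DUTY: dict[str, float] = {
    "tripod-A": 0.5,
    "tripod-B": 0.5,
    "tripod-C": 0.5,
    "bipod-A": 1 / 3,
    "bipod-B": 1 / 3,
    "bipod-C": 1 / 3,
    "wave": 5 / 6,
    "tetrapod": 2 / 3,
}


@dataclass(frozen=True)
class NoiseModel:
    """Annotation-noise parameters for synthetic footfall trials.

    ``onset_jitter_sd`` shifts every stance/swing boundary by a rounded
    Gaussian number of frames; ``slip_insert_rate`` is the probability per
    stance bout of a spurious 1-3 frame swing (a slip); ``dropout_rate`` is
    the probability per swing bout of a spurious 1-3 frame stance blip.
    """

    onset_jitter_sd: float = 0.0
    slip_insert_rate: float = 0.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_jitter_sd < 0:
            raise ValueError("jitter must be >= 0")
        for r in (self.slip_insert_rate, self.dropout_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def is_silent(self) -> bool:
        return (
            self.onset_jitter_sd == 0
            and self.slip_insert_rate == 0
            and self.dropout_rate == 0
        )


#: Moderate manual-annotation noise used as the study default.
MODERATE_NOISE = NoiseModel(onset_jitter_sd=1.5, slip_insert_rate=0.10, dropout_rate=0.10)


def _bouts(trace: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean trace into (start, stop, value) bouts."""
    trace = np.asarray(trace, bool)
    edges = np.flatnonzero(np.diff(trace)) + 1
    starts = np.concatenate(([0], edges))
    stops = np.concatenate((edges, [len(trace)]))
    return [(int(a), int(b), bool(trace[a])) for a, b in zip(starts, stops)]


def _apply_noise(trace: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    n = len(trace)
    out = trace.copy()
    if noise.onset_jitter_sd > 0:
        bounds = np.flatnonzero(np.diff(trace)) + 1
        shifted = bounds + np.rint(
            rng.normal(0.0, noise.onset_jitter_sd, len(bounds))
        ).astype(int)
        shifted = np.clip(np.sort(shifted), 0, n)
        out = np.empty(n, dtype=bool)
        value = bool(trace[0])
        prev = 0
        for b in list(shifted) + [n]:
            out[prev:b] = value
            value = not value
            prev = b
    # spurious short bouts
    for start, stop, val in _bouts(out):
        length = stop - start
        if length < 4:
            continue
        rate = noise.slip_insert_rate if val else noise.dropout_rate
        if rate > 0 and rng.uniform() < rate:
            blip = min(int(rng.integers(1, 4)), length - 2)
            pos = int(rng.integers(start + 1, stop - blip))
            out[pos:pos + blip] = not val
    return out


def generate_fly_trial(
    class_name: str,
    cycles: int = 4,
    frame_rate: float = 500.0,
    stride_frequency: float = 20.0,
    duty: float | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> FootfallDiagram:
    """Synthetic fly footfall trial of a named gait class.

    Renders the class's ideal diagram at ``frame_rate`` (500 fps videography
    default) and ``stride_frequency`` (20 Hz fast walking), then applies the
    annotation-noise model.  Deterministic for a fixed seed.  With all-zero
    noise the output is byte-identical to :func:`hexagait.gaits.ideal_footfall`.
    """
    if class_name not in CLASS_VECTORS and class_name != "random":
        raise ValueError(f"unknown gait class {class_name!r}")
    if cycles < 4:
        raise ValueError("need >= 4 cycles for three-stride TCS windowing")
    rng = np.random.default_rng(seed)
    if class_name == "random":
        vector = GaitPhaseVector.from_free(rng.uniform(0, 360, 5))
        duty = duty if duty is not None else 0.5
    else:
        vector = CLASS_VECTORS[class_name]
        duty = duty if duty is not None else CLASS_DUTY[class_name]
    fpc = int(round(frame_rate / stride_frequency))
    diagram = ideal_footfall(
        vector, duty, cycles, fpc, frame_rate=frame_rate, source="synthetic"
    )
    noise = noise or NoiseModel()
    if noise.is_silent:
        return diagram
    stance = np.column_stack(
        [_apply_noise(diagram.stance[:, i], noise, rng) for i in range(6)]
    )
    return FootfallDiagram(
        stance=stance, frame_rate=frame_rate, source="synthetic", frames_per_cycle=fpc
    )


def generate_incline_dataset(
    mu_s_true: float,
    n_trials: int,
    angle_noise_sd: float = 2.0,
    seed: int | None = None,
) -> np.ndarray:
    """Slide-onset tilt angles (degrees) around arctan of the true mu_s."""
    if mu_s_true <= 0:
        raise ValueError("true friction coefficient must be positive")
    rng = np.random.default_rng(seed)
    base = np.degrees(np.arctan(mu_s_true))
    return base + rng.normal(0.0, angle_noise_sd, n_trials)


def estimate_friction_coefficient(angles_deg: np.ndarray) -> float:
    """Recover mu_s as tan of the mean slide-onset angle."""
    return float(np.tan(np.radians(np.mean(angles_deg))))
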