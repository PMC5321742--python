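"""Footfall-diagram metrics and locomotor performance measures.

Implements the study's gait statistics on any :class:`FootfallDiagram`,
whether simulated, synthetic or manually annotated from videography:

* **TCS** (Tripod Coordination Strength): over a three-stride window anchored
  to right-front-leg (R1) stance onsets, the fraction of time the stance set
  is *exactly* one of the two tripod triangles {R1, L2, R3} or {L1, R2, L3}.
* **Atypical bipod-like coordination strength**: over the same window, the
  fraction of time any of the designated leg pairs — contralateral front/rear
  (L1+R3 or R1+L3) or the two middle legs (L2+R2) — are simultaneously in
  swing.
* Mean stance count and per-leg duty factors over five stride cycles (the
  first cycle is omitted to reach steady state whenever enough data exists).
* Static-stability: percentage of time the projected COM lies inside the
  convex support polygon of the stance feet (cycles 2-10 of a ten-cycle run).
* Cost of transport COT = E / (m g d) and the tilt-test static friction
  coefficient mu_s = tan(theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point

from .footfall import LEG_INDEX, LEGS, FootfallDiagram
from .simulator import BodyModel, SimulationResult

__all__ = [
    "InsufficientDataError",
    "EnergyAccounting",
    "tcs",
    "bipod_coordination_strength",
    "mean_stance_count",
    "duty_factors",
    "point_in_convex_support",
    "static_stability_fraction",
    "cost_of_transport",
    "static_friction_coefficient",
    "classify_fly_trial",
    "compute_metrics",
]

# leg-index sets for the two tripod support triangles
_TRIPOD_SETS = (
    frozenset({LEG_INDEX["R1"], LEG_INDEX["L2"], LEG_INDEX["R3"]}),
    frozenset({LEG_INDEX["L1"], LEG_INDEX["R2"], LEG_INDEX["L3"]}),
)
# leg-index pairs whose co-swing defines atypical bipod-like coordination
_BIPOD_PAIRS = (
    (LEG_INDEX["L1"], LEG_INDEX["R3"]),
    (LEG_INDEX["R1"], LEG_INDEX["L3"]),
    (LEG_INDEX["L2"], LEG_INDEX["R2"]),
)


class InsufficientDataError(ValueError):
    """Raised when a diagram is too short for the requested windowing."""


def _stance_onsets(trace: np.ndarray) -> np.ndarray:
    """Frame indices where a leg enters stance (rising edges)."""
    trace = np.asarray(trace, bool)
    edges = np.flatnonzero(~trace[:-1] & trace[1:]) + 1
    if trace[0]:
        edges = np.concatenate(([0], edges))
    return edges


def _tcs_window(diagram: FootfallDiagram) -> tuple[int, int]:
    """Three-R1-stride analysis window [start, stop) in frames.

    The window runs from an R1 stance onset to the final R1 swing frame three
    walking cycles later (i.e. up to the fourth onset).  For simulated
    diagrams, which lack a touch-evoked start, the window is anchored at the
    first R1 onset after the first full cycle; annotated and synthetic trials
    start at the first R1 onset.
    """
    onsets = _stance_onsets(diagram.leg("R1"))
    if diagram.source == "simulated" and diagram.frames_per_cycle:
        onsets = onsets[onsets >= diagram.frames_per_cycle]
    if len(onsets) < 4:
        raise InsufficientDataError(
            "need at least three complete R1 step cycles for TCS windowing"
        )
    return int(onsets[0]), int(onsets[3])


def tcs(diagram: FootfallDiagram) -> float:
    """Tripod Coordination Strength: t2 / t1 over a three-cycle window.

    A frame counts toward t2 iff the stance set equals {R1, L2, R3} or
    {L1, R2, L3} *exactly* — no extra legs down.
    """
    start, stop = _tcs_window(diagram)
    window = diagram.stance[start:stop]
    sets = [frozenset(np.flatnonzero(row)) for row in window]
    t2 = sum(s in _TRIPOD_SETS for s in sets)
    return t2 / len(sets)


def bipod_coordination_strength(diagram: FootfallDiagram) -> float:
    """Fraction of the TCS window with a designated leg pair co-swinging."""
    start, stop = _tcs_window(diagram)
    window = diagram.stance[start:stop]
    swing = ~window
    co = np.zeros(len(window), dtype=bool)
    for a, b in _BIPOD_PAIRS:
        co |= swing[:, a] & swing[:, b]
    return float(co.mean())


def _cycle_window(diagram: FootfallDiagram, n_cycles: int) -> tuple[int, int, int]:
    """(start, stop, frames_per_cycle) covering ``n_cycles`` steady cycles."""
    fpc = diagram.frames_per_cycle
    if fpc is None:
        onsets = _stance_onsets(diagram.leg("R1"))
        if len(onsets) < 2:
            raise InsufficientDataError("cannot estimate cycle length from R1 onsets")
        fpc = int(round(float(np.median(np.diff(onsets)))))
    total = diagram.n_frames // fpc
    if total < n_cycles:
        raise InsufficientDataError(f"diagram spans {total} cycles, need {n_cycles}")
    start = fpc if total >= n_cycles + 1 else 0  # omit first cycle when possible
    return start, start + n_cycles * fpc, fpc


def mean_stance_count(diagram: FootfallDiagram, n_cycles: int = 5) -> float:
    """Average number of legs in stance over ``n_cycles`` walking cycles."""
    start, stop, _ = _cycle_window(diagram, n_cycles)
    return float(diagram.stance[start:stop].sum(axis=1).mean())


def duty_factors(diagram: FootfallDiagram, n_cycles: int = 5) -> pd.Series:
    """Per-leg stance fraction over ``n_cycles`` cycles (duty < 0.5 = running)."""
    start, stop, _ = _cycle_window(diagram, n_cycles)
    return pd.Series(diagram.stance[start:stop].mean(axis=0), index=list(LEGS))


def point_in_convex_support(com_projection, stance_feet) -> bool:
    """Is the projected COM inside (or on) the convex hull of the stance feet?

    Fewer than three contacts, or collinear contacts, never form a support
    polygon and return ``False`` by convention.
    """
    feet = np.atleast_2d(np.asarray(stance_feet, float)) if len(stance_feet) else np.empty((0, 2))
    if feet.shape[0] < 3:
        return False
    hull = MultiPoint([tuple(p) for p in feet]).convex_hull
    if hull.geom_type != "Polygon":  # degenerate: point or line
        return False
    return bool(hull.covers(Point(*np.asarray(com_projection, float))))


def static_stability_fraction(
    result: SimulationResult,
    model: BodyModel | None = None,
    n_cycles: int = 9,
) -> float:
    """Percent of time the COM projection falls inside the support polygon.

    Evaluated over cycles 2..(1+n_cycles) of the run (the first cycle is
    omitted to reach steady state), using the simulator's prescribed planar
    foot positions; the COM projects to the body-frame origin.
    """
    model = model or result.model
    fpc = result.footfall.frames_per_cycle
    assert fpc is not None
    total = result.footfall.n_frames // fpc
    if total < n_cycles + 1:
        raise InsufficientDataError(
            f"run spans {total} cycles, need {n_cycles + 1} for stability analysis"
        )
    start, stop = fpc, (n_cycles + 1) * fpc
    hits = 0
    for t in range(start, stop):
        feet = result.foot_positions[t][result.footfall.stance[t]]
        hits += point_in_convex_support((0.0, 0.0), feet)
    return 100.0 * hits / (stop - start)


@dataclass(frozen=True)
class EnergyAccounting:
    """Energy ledger for the cost-of-transport computation."""

    energy: float     # J, integral of summed |torque * angular velocity|
    mass: float       # kg
    distance: float   # m
    g: float = 9.81
    duration: float = 0.5

    def __post_init__(self) -> None:
        if self.energy < 0 or self.distance < 0:
            raise ValueError("energy and distance must be non-negative")


def cost_of_transport(acct: EnergyAccounting | SimulationResult) -> float:
    """Dimensionless COT = E / (m g d)."""
    if isinstance(acct, SimulationResult):
        acct = EnergyAccounting(
            energy=acct.energy,
            mass=acct.model.body_mass,
            distance=max(0.0, acct.distance),
            g=acct.condition.g,
            duration=acct.duration,
        )
    if acct.distance == 0:
        raise ZeroDivisionError("cost of transport undefined for zero distance")
    return acct.energy / (acct.mass * acct.g * acct.distance)


def static_friction_coefficient(theta_deg: float) -> float:
    """Static friction coefficient from the slide-onset tilt angle: tan(theta)."""
    if not 0.0 <= theta_deg < 90.0:
        raise ValueError("tilt angle must lie in [0, 90) degrees")
    return float(np.tan(np.radians(theta_deg)))


def classify_fly_trial(diagram: FootfallDiagram, margin: float = 0.05) -> str:
    """Coarse tripod-vs-bipod call from the two coordination metrics.

    Used for annotated or synthetic fly trials where no phase vector exists:
    whichever of TCS and bipod-coordination strength dominates (by at least
    ``margin``) names the family; otherwise "unclear".  A trial too mangled
    to anchor the three-stride window is likewise "unclear".
    """
    try:
        t = tcs(diagram)
        b = bipod_coordination_strength(diagram)
    except InsufficientDataError:
        return "unclear"
    if t > b + margin:
        return "tripod"
    if b > t + margin:
        return "bipod"
    return "unclear"


def compute_metrics(diagram: FootfallDiagram, n_cycles: int = 5) -> dict[str, float]:
    """Convenience bundle of the footfall metrics for one diagram.

    Metrics whose windowing the diagram cannot support come back as NaN.
    """
    out: dict[str, float] = {}
    for name, fn in (
        ("tcs", lambda d: tcs(d)),
        ("bipod_coordination", lambda d: bipod_coordination_strength(d)),
        ("mean_stance_count", lambda d: mean_stance_count(d, n_cycles)),
        ("duty_factor_mean", lambda d: float(duty_factors(d, n_cycles).mean())),
    ):
        try:
            out[name] = fn(diagram)
        except InsufficientDataError:
            out[name] = float("nan")
    return out
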