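"""Kinematic mapping from the model's planar leg to a two-link robot leg.

The model leg is a planar serial chain of four segments (lengths a, b, c, d
proximal to distal) with cumulative joint angles (alpha, beta, gamma,
epsilon); the hexapod robot has only two flexion/extension segments (e, f)
per leg plus a promotion/remotion joint that is passed through directly.

Both chains use a straight-down zero-angle convention: with all joint angles
at zero the leg points along -y, and positive angles rotate distal segments
forward (+x).  Forward kinematics of the model chain give the leg-tip path in
the leg's plane of motion; a closed-form two-link inverse kinematics places
the robot's leg tip on the same (scaled) path.  Of the two algebraic IK
branches the physically feasible one is selected (knee-backward by default),
and a configurable promotion bias widens the robot's promotion range to match
the model's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .footfall import LEGS
from .gaits import GaitPhaseVector
from .simulator import BodyModel, StepTrajectoryParams, prescribed_foot_state

__all__ = [
    "PlanarLegChain",
    "TwoLinkLeg",
    "UnreachableTargetError",
    "InfeasibleSolutionError",
    "leg_tip_position",
    "two_link_ik",
    "two_link_fk",
    "select_feasible",
    "model_tip_path",
    "map_gait_to_robot",
]


class UnreachableTargetError(ValueError):
    """Target outside the two-link workspace; carries the reach interval."""

    def __init__(self, target, reach_min: float, reach_max: float, phase: float | None = None):
        self.reach_min, self.reach_max, self.phase = reach_min, reach_max, phase
        at = f" at cycle phase {phase:.3f}" if phase is not None else ""
        super().__init__(
            f"target {tuple(np.round(target, 6))} outside reach "
            f"[{reach_min:.6g}, {reach_max:.6g}]{at}"
        )


class InfeasibleSolutionError(ValueError):
    """No IK branch satisfies the robot's joint limits."""


@dataclass(frozen=True)
class PlanarLegChain:
    """Four-segment planar leg: lengths proximal->distal plus joint angles."""

    lengths: tuple[float, float, float, float]            # a, b, c, d
    angles: tuple[float, float, float, float] = (0, 0, 0, 0)  # alpha, beta, gamma, epsilon (deg)

    def __post_init__(self) -> None:
        if len(self.lengths) != 4 or len(self.angles) != 4:
            raise ValueError("four segment lengths and four joint angles required")
        if min(self.lengths) <= 0:
            raise ValueError("all segment lengths must be positive")


@dataclass(frozen=True)
class TwoLinkLeg:
    """Two-segment robot leg with joint limits and promotion bias (degrees)."""

    e: float = 1.0
    f: float = 1.0
    lambda_limits: tuple[float, float] = (-135.0, 135.0)
    sigma_limits: tuple[float, float] = (-150.0, 150.0)
    promotion_bias: float = 0.0
    prefer_knee_backward: bool = True

    def __post_init__(self) -> None:
        if self.e <= 0 or self.f <= 0:
            raise ValueError("segment lengths must be positive")

    @property
    def reach(self) -> tuple[float, float]:
        return abs(self.e - self.f), self.e + self.f


def leg_tip_position(chain: PlanarLegChain) -> tuple[float, float]:
    """Forward kinematics of the four-segment chain.

    x = sum_k l_k sin(Theta_k), y = -sum_k l_k cos(Theta_k) with Theta_k the
    cumulative joint angle through segment k; all angles zero = straight down.
    """
    theta = np.cumsum(np.radians(chain.angles))
    l = np.asarray(chain.lengths, float)
    return float(np.sum(l * np.sin(theta))), float(-np.sum(l * np.cos(theta)))


def two_link_fk(leg: TwoLinkLeg, lam: float, sigma: float) -> tuple[float, float]:
    """Forward kinematics of the two-link leg (angles in degrees)."""
    t1 = math.radians(lam)
    t2 = t1 + math.radians(sigma)
    return (
        leg.e * math.sin(t1) + leg.f * math.sin(t2),
        -leg.e * math.cos(t1) - leg.f * math.cos(t2),
    )


def two_link_ik(target, leg: TwoLinkLeg, tol: float = 1e-9) -> list[tuple[float, float]]:
    """Both algebraic (lambda, sigma) solutions reaching ``target`` (degrees).

    Solutions are verified by forward substitution to within ``tol`` length
    units.  A boundary target (straight leg) yields a single solution.
    Raises :class:`UnreachableTargetError` outside the reach annulus.
    """
    x, y = float(target[0]), float(target[1])
    r = math.hypot(x, y)
    lo, hi = leg.reach
    if r < lo - tol or r > hi + tol:
        raise UnreachableTargetError(target, lo, hi)
    cos_sig = (r * r - leg.e**2 - leg.f**2) / (2.0 * leg.e * leg.f)
    cos_sig = min(1.0, max(-1.0, cos_sig))
    sig = math.acos(cos_sig)
    solutions = []
    for s in ({sig} if sig in (0.0, math.pi) else {sig, -sig}):
        lam = math.atan2(x, -y) - math.atan2(leg.f * math.sin(s), leg.e + leg.f * math.cos(s))
        cand = (math.degrees(lam), math.degrees(s))
        fx, fy = two_link_fk(leg, *cand)
        if math.hypot(fx - x, fy - y) > max(tol, 1e-9 * max(1.0, r)):
            raise AssertionError("IK solution failed forward-substitution check")
        solutions.append(cand)
    solutions.sort()
    return solutions


def select_feasible(
    solutions: list[tuple[float, float]],
    leg: TwoLinkLeg,
    bias: float | None = None,
) -> tuple[float, float]:
    """Pick one IK branch: filter by joint limits, prefer knee-backward.

    The configured promotion ``bias`` (degrees) is added to the selected
    proximal angle.  Raises :class:`InfeasibleSolutionError` when no branch
    fits the limits.
    """
    if not solutions:
        raise InfeasibleSolutionError("empty solution set")
    bias = leg.promotion_bias if bias is None else bias
    lo_l, hi_l = leg.lambda_limits
    lo_s, hi_s = leg.sigma_limits
    feasible = [
        (lam, sig)
        for lam, sig in solutions
        if lo_l <= lam <= hi_l and lo_s <= sig <= hi_s
    ]
    if not feasible:
        raise InfeasibleSolutionError(f"no solution within joint limits: {solutions}")
    # knee-backward branch: distal joint flexed backward (sigma <= 0)
    key = (min if leg.prefer_knee_backward else max)
    lam, sig = key(feasible, key=lambda p: p[1])
    return lam + bias, sig


def model_tip_path(
    leg: str,
    gait: GaitPhaseVector,
    model: BodyModel,
    traj: StepTrajectoryParams,
    samples_per_cycle: int,
) -> np.ndarray:
    """Sampled model leg-tip path in the leg's plane of motion.

    Returns an ``(n, 2)`` array of (fore-aft, vertical) positions relative to
    the hip, derived from the simulator's prescribed foot trajectory: the
    vertical coordinate is the (negative) COM standoff plus the swing lift.
    """
    pts = np.empty((samples_per_cycle, 2))
    f = model.stride_frequency
    home = model.feet[LEGS.index(leg)]
    for k in range(samples_per_cycle):
        t = k / (samples_per_cycle * f)
        pos, _, _ = prescribed_foot_state(leg, t, gait, traj, model)
        pts[k, 0] = pos[0] - home[0]
        pts[k, 1] = -model.com_height + pos[2]
    return pts


def map_gait_to_robot(
    gait: GaitPhaseVector,
    leg: TwoLinkLeg,
    model: BodyModel | None = None,
    traj: StepTrajectoryParams | None = None,
    samples_per_cycle: int = 50,
    workspace_fraction: float = 0.8,
) -> pd.DataFrame:
    """Map a model gait onto robot joint-angle time series (one cycle).

    The model's prescribed leg-tip path is scaled uniformly so its farthest
    point sits at ``workspace_fraction`` of the robot leg's maximal reach,
    then inverse kinematics is solved per sample and per leg.  Relative leg
    phases are preserved exactly (the mapping is per-leg and time-invariant).
    Returns a tidy frame (t, leg, promotion, lambda_deg, sigma_deg).
    """
    model = model or BodyModel()
    traj = traj or StepTrajectoryParams()
    f = model.stride_frequency
    rows = []
    for leg_name in LEGS:
        path = model_tip_path(leg_name, gait, model, traj, samples_per_cycle)
        radius = np.hypot(path[:, 0], path[:, 1]).max()
        scale = workspace_fraction * leg.reach[1] / radius
        scaled = path * scale
        for k, (x, y) in enumerate(scaled):
            t = k / (samples_per_cycle * f)
            phase = k / samples_per_cycle
            try:
                sols = two_link_ik((x, y), leg)
            except UnreachableTargetError as err:
                raise UnreachableTargetError((x, y), *leg.reach, phase=phase) from err
            lam, sig = select_feasible(sols, leg, bias=0.0)
            # promotion: small-angle fore-aft swing of the whole leg plane,
            # widened by the configured promotion bias
            promotion = math.degrees(math.atan2(x, leg.reach[1])) + leg.promotion_bias
            rows.append(
                {
                    "t": t,
                    "leg": leg_name,
                    "promotion": promotion,
                    "lambda_deg": lam,
                    "sigma_deg": sig,
                }
            )
    return pd.DataFrame(rows)
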