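"""Quasi-static template simulator for phase-encoded hexapod locomotion.

The model is a fly-scale hexapod (2.5 mm, 0.85 mg) whose six feet follow
prescribed periodic trajectories: during a fraction ``kappa`` of each 20 Hz
cycle a foot sweeps backward along the substrate (power stroke), otherwise it
returns forward through a swing arc.  Only the relative phases of the six leg
cycles differ between gaits; the left front leg (L1) is fixed at phase 0.

Rather than integrating rigid-body dynamics, the template resolves each time
step quasi-statically:

* the body advances at the sweep speed of its sticking feet,
* contact normal loads share body weight (plus any adhesion force) equally,
* a Coulomb friction pyramid (``mu_pyramid`` per tangential axis) bounds the
  tangential force each contact can carry — insufficient friction scales the
  advance down (slipping),
* on vertical surfaces a *peel* bookkeeping term accumulates while the
  contact set cannot statically hold the body (fewer than three non-collinear
  contacts, or projected COM outside the support polygon) and the model falls
  once it exceeds a threshold; losing all load-bearing contacts makes the
  body slide backwards and eventually fall.

Adhesion is a constant surface-normal force per contacting foot, expressed as
a percentage of the force needed for a single foot to suspend the body
inverted (100% = one body weight).  It feeds the friction pyramid, so it also
makes tangential slipping harder — the template abstraction of claws/pulvilli.

The closed-form physics of the source system (P-controller servo velocity,
sliding-friction and drag estimates, Froude frequency scaling) are exposed as
standalone functions; the servo law does not drive the template but is kept
for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json
import math

import numpy as np
import pandas as pd

from .footfall import LEGS, FootfallDiagram
from .gaits import GaitPhaseVector, cycle_position

__all__ = [
    "BodyModel",
    "StepTrajectoryParams",
    "SimulationCondition",
    "ControllerParams",
    "SolverParams",
    "SimState",
    "SimulationResult",
    "servo_velocity",
    "sliding_friction_estimate",
    "friction_limit",
    "adhesion_force",
    "drag_force",
    "froude_scaled_frequency",
    "leg_tip_speed",
    "gravity_components",
    "prescribed_foot_state",
    "step",
    "simulate",
]

ORIENTATIONS = ("ground", "wall_up", "wall_down", "wall_side")

# fore-aft (x, heading) and lateral (y) foot home positions, metres;
# mirror-symmetric, middle feet slightly wider than front/rear.
_DEFAULT_FEET = (
    (+1.25e-3, -0.75e-3),  # L1
    (+1.25e-3, +0.75e-3),  # R1
    (0.0, -0.85e-3),       # L2
    (0.0, +0.85e-3),       # R2
    (-1.25e-3, -0.75e-3),  # L3
    (-1.25e-3, +0.75e-3),  # R3
)


@dataclass(frozen=True)
class BodyModel:
    """Morphology and gait-cycle constants of the hexapod model."""

    body_mass: float = 8.5e-7          # kg (0.85 mg adult female fly)
    leg_mass: float = 1.42e-7          # kg per leg
    body_length: float = 2.5e-3        # m
    com_height: float = 1.0e-3         # m, COM standoff above the surface
    stride_frequency: float = 20.0     # Hz
    foot_home_positions: tuple = _DEFAULT_FEET

    def __post_init__(self) -> None:
        for name in ("body_mass", "leg_mass", "body_length", "com_height", "stride_frequency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        feet = np.asarray(self.foot_home_positions, dtype=float)
        if feet.shape != (6, 2):
            raise ValueError("six planar foot home positions required")
        # L/R mirror symmetry: lateral coordinates negate between pair members
        left, right = feet[0::2], feet[1::2]
        if not (np.allclose(left[:, 0], right[:, 0]) and np.allclose(left[:, 1], -right[:, 1])):
            raise ValueError("foot home positions must be left/right mirror-symmetric")

    @property
    def feet(self) -> np.ndarray:
        return np.asarray(self.foot_home_positions, dtype=float)


@dataclass(frozen=True)
class StepTrajectoryParams:
    """Prescribed foot trajectory: ground-contact window and sweep geometry."""

    contact_fraction: float = 0.4   # kappa: fraction of cycle at surface level
    sweep_length: float = 1.0e-3    # m, fore-aft sweep per power stroke
    swing_clearance: float = 0.5e-3  # m, peak foot lift during swing

    def __post_init__(self) -> None:
        if not 0.0 < self.contact_fraction < 1.0:
            raise ValueError("contact_fraction must lie in (0, 1)")
        if self.sweep_length <= 0 or self.swing_clearance <= 0:
            raise ValueError("sweep_length and swing_clearance must be positive")

    def sweep_speed(self, stride_frequency: float) -> float:
        """Foot speed relative to the body during the power stroke (m/s)."""
        return self.sweep_length * stride_frequency / self.contact_fraction


@dataclass(frozen=True)
class SimulationCondition:
    """Surface orientation, adhesion level and friction bound."""

    orientation: str = "ground"
    adhesion_level: float = 0.0     # percent of single-foot suspension force
    mu_pyramid: float = 4.0         # friction bound per tangential axis
    g: float = 9.81                 # m/s^2

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if self.adhesion_level < 0:
            raise ValueError("adhesion_level must be >= 0")
        if self.mu_pyramid <= 0:
            raise ValueError("mu_pyramid must be positive")

    @property
    def is_wall(self) -> bool:
        return self.orientation != "ground"


@dataclass(frozen=True)
class ControllerParams:
    """P-controller servo parameters (kept for the closed-form servo law)."""

    gain: float = 10.0       # 1/s
    max_velocity: float = 5.0  # rad/s

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.max_velocity <= 0:
            raise ValueError("gain and max_velocity must be positive")


@dataclass(frozen=True)
class SolverParams:
    """Quasi-static contact solver constants.

    ``j_peel`` converts the gravity peel torque (mass * |g_heading| *
    com_height) into a peel-angle growth rate; the model falls on a wall when
    the accumulated peel exceeds ``theta_peel_max`` or it spends longer than
    ``tau_air_max`` consecutively without a load-bearing contact.  Defaults
    are calibrated so that the ideal tripod climbs a vertical wall at 200%
    adhesion while the ideal bipod (permanently two contacts) peels off.
    """

    mu_slide: float = 0.1           # sliding-friction coefficient for leg drag
    gamma_slip: float = 200.0       # 1/s, back-slide rate divisor on walls
    j_peel: float = 4.2e-10         # N m s, peel "admittance"
    theta_peel_max: float = 0.3     # peel-angle threshold before falling
    tau_air_max: float = 0.010      # s, max consecutive unsupported time
    support_margin: float = 1.0e-4  # m, COM must sit this far inside the hull
    require_com_support: bool = True
    eps_force: float = 1e-15        # N, threshold below which friction is nil


# --------------------------------------------------------------------------
# closed-form physics
# --------------------------------------------------------------------------
def servo_velocity(P: float, p_t: float, p_c: float, v_d: float) -> float:
    """P-controller joint velocity: proportional, saturated at ``v_d``."""
    if P <= 0 or v_d <= 0:
        raise ValueError("P and v_d must be positive")
    err = p_t - p_c
    return math.copysign(min(P * abs(err), v_d), err) if err else 0.0


def sliding_friction_estimate(mu: float, m: float, g: float = 9.81) -> float:
    """Sliding friction force magnitude mu*m*g (N)."""
    if mu < 0 or m < 0 or g < 0:
        raise ValueError("inputs must be non-negative")
    return mu * m * g


def friction_limit(F_n: float, mu_pyramid: float) -> float:
    """Per-tangential-axis friction bound of the pyramid: mu * F_n."""
    if F_n < 0:
        raise ValueError("normal force must be non-negative")
    return mu_pyramid * F_n


def adhesion_force(level: float, body_mass: float, g: float = 9.81) -> float:
    """Constant normal force per contacting foot for a given adhesion level.

    100% is the force for one foot to suspend the body inverted, i.e. one
    body weight; 200% (the study level) is twice the body weight per contact.
    """
    if level < 0:
        raise ValueError("adhesion level must be >= 0")
    return (level / 100.0) * body_mass * g


def drag_force(rho: float, c_D: float, A: float, v: float) -> float:
    """Aerodynamic drag 0.5 * rho * c_D * A * v^2 (N)."""
    if min(rho, c_D, A, v) < 0:
        raise ValueError("inputs must be non-negative")
    return 0.5 * rho * c_D * A * v * v


def froude_scaled_frequency(f: float, L: float, L_target: float) -> float:
    """Stride frequency at a new body length holding the Froude number f^2 L/g."""
    if min(f, L, L_target) <= 0:
        raise ValueError("inputs must be strictly positive")
    return f * math.sqrt(L / L_target)


def leg_tip_speed(f: float, L: float) -> float:
    """Circumferential leg-tip speed 2*pi*f*L of a rotating leg of length L."""
    return 2.0 * math.pi * f * L


def gravity_components(condition: SimulationCondition) -> tuple[float, float, float]:
    """Gravity in body axes (heading, lateral, surface-normal), m/s^2.

    Upward climbing pulls the model backward along its heading, downward
    climbing pulls it forward, sideways climbing pulls it laterally; on the
    ground gravity presses the model onto the substrate.
    """
    g = condition.g
    return {
        "ground": (0.0, 0.0, -g),
        "wall_up": (-g, 0.0, 0.0),
        "wall_down": (+g, 0.0, 0.0),
        "wall_side": (0.0, -g, 0.0),
    }[condition.orientation]


# --------------------------------------------------------------------------
# prescribed foot kinematics
# --------------------------------------------------------------------------
def prescribed_foot_state(
    leg: str | int,
    t: float,
    gait: GaitPhaseVector,
    traj: StepTrajectoryParams,
    model: BodyModel,
) -> tuple[np.ndarray, bool, float]:
    """Prescribed foot position (body frame), surface contact flag, sweep speed.

    Cycle position ``c = (t*f + phase/360) mod 1``.  For ``c < kappa`` the
    foot is at surface level, its fore-aft offset ramping linearly from +s/2
    to -s/2 (backward power stroke); otherwise it is lifted by a smooth arc of
    height ``swing_clearance`` while returning forward.  The returned speed is
    the foot's fore-aft speed relative to the body (positive = propulsive
    backward sweep during stance, forward return during swing).
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    idx = leg if isinstance(leg, int) else LEGS.index(leg)
    f = model.stride_frequency
    kappa, s = traj.contact_fraction, traj.sweep_length
    c = cycle_position(t * f + gait.phases[idx] / 360.0)
    home = model.feet[idx]
    if c < kappa - 1e-9:
        offset = s / 2.0 - s * (c / kappa)
        pos = np.array([home[0] + offset, home[1], 0.0])
        return pos, True, traj.sweep_speed(f)
    u = (c - kappa) / (1.0 - kappa)
    offset = -s / 2.0 + s * u
    z = traj.swing_clearance * math.sin(math.pi * u)
    pos = np.array([home[0] + offset, home[1], z])
    return pos, False, s * f / (1.0 - kappa)


def _contact_matrix(
    gait: GaitPhaseVector,
    model: BodyModel,
    traj: StepTrajectoryParams,
    times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (frames x 6) contact mask and fore-aft foot offsets."""
    f = model.stride_frequency
    kappa, s = traj.contact_fraction, traj.sweep_length
    c = cycle_position(times[:, None] * f + gait.as_array()[None, :] / 360.0)
    contact = c < kappa - 1e-9
    offset = np.where(
        contact,
        s / 2.0 - s * (c / kappa),
        -s / 2.0 + s * (c - kappa) / (1.0 - kappa),
    )
    return contact, offset


# --------------------------------------------------------------------------
# support-pattern geometry
# --------------------------------------------------------------------------
def _com_support_depth(feet: np.ndarray) -> float:
    """Signed distance of the origin (COM projection) inside the convex hull.

    Positive depth: strictly interior by that margin.  Returns -inf for fewer
    than three points or a degenerate (collinear) hull.
    """
    pts = np.asarray(feet, float)
    if len(pts) < 3:
        return -math.inf
    # convex hull by angular sort around the centroid (<= 6 points)
    centroid = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0]))
    ring = pts[order]
    # keep only hull vertices (drop reflex points) via cross-product check
    hull: list[np.ndarray] = []
    m = len(ring)
    for i in range(m):
        hull.append(ring[i])
    # gift-wrap style pruning: iterate until all turns are left turns
    changed = True
    while changed and len(hull) >= 3:
        changed = False
        pruned = []
        k = len(hull)
        for i in range(k):
            a, b, c = hull[i - 1], hull[i], hull[(i + 1) % k]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross > 0:
                pruned.append(b)
            else:
                changed = True
        hull = pruned
    if len(hull) < 3:
        return -math.inf
    arr = np.array(hull)
    nxt = np.roll(arr, -1, axis=0)
    edges = nxt - arr
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    if np.any(lengths < 1e-15):
        return -math.inf
    # signed distance of origin to each edge (positive = left of CCW edge)
    cross = edges[:, 0] * (-arr[:, 1]) - edges[:, 1] * (-arr[:, 0])
    return float(np.min(cross / lengths))


_PATTERN_CACHE: dict[tuple, np.ndarray] = {}


def _pattern_table(model: BodyModel, solver: SolverParams) -> np.ndarray:
    """For each 6-bit contact mask: can the pattern statically hold the body?

    Requires at least three contacts forming a non-degenerate polygon; when
    ``require_com_support`` is set, the projected COM must additionally lie at
    least ``support_margin`` inside the support hull (home foot positions).
    """
    key = (
        model.feet.tobytes(),
        solver.support_margin,
        solver.require_com_support,
    )
    cached = _PATTERN_CACHE.get(key)
    if cached is not None:
        return cached
    feet = model.feet
    ok = np.zeros(64, dtype=bool)
    for mask in range(64):
        idx = [i for i in range(6) if mask >> i & 1]
        if len(idx) < 3:
            continue
        depth = _com_support_depth(feet[idx])
        if solver.require_com_support:
            ok[mask] = depth >= solver.support_margin
        else:
            ok[mask] = depth > -math.inf
    _PATTERN_CACHE[key] = ok
    return ok


# --------------------------------------------------------------------------
# stepping
# --------------------------------------------------------------------------
@dataclass
class SimState:
    """Mutable per-step state of the quasi-static model."""

    t: float = 0.0
    position: float = 0.0
    peel: float = 0.0
    airborne: float = 0.0
    energy: float = 0.0
    fell: bool = False
    fall_time: float | None = None


def step(
    state: SimState,
    t: float,
    gait: GaitPhaseVector,
    condition: SimulationCondition,
    model: BodyModel,
    traj: StepTrajectoryParams,
    solver: SolverParams,
    dt: float,
    _pattern_ok: np.ndarray | None = None,
) -> tuple[SimState, np.ndarray, np.ndarray, float]:
    """Advance one time step; returns (state', contact row, forces, speed).

    Forces are per-leg ``(tangential, normal)`` in newtons (zero off contact).
    This scalar implementation is the reference for the vectorized
    :func:`simulate`; both produce identical trajectories.
    """
    if dt <= 0 or dt > 1.0 / (4.0 * model.stride_frequency):
        raise ValueError("dt must be positive and at most a quarter cycle")
    forces = np.zeros((6, 2))
    if state.fell:
        return state, np.zeros(6, bool), forces, 0.0
    if _pattern_ok is None:
        _pattern_ok = _pattern_table(model, solver)

    contact = np.array(
        [prescribed_foot_state(i, t, gait, traj, model)[1] for i in range(6)]
    )
    n_c = int(contact.sum())
    g_h, g_l, g_n = gravity_components(condition)
    g_tan = math.hypot(g_h, g_l)  # in-plane gravity (heading + lateral)
    F_ad = adhesion_force(condition.adhesion_level, model.body_mass, condition.g)
    v_sweep = traj.sweep_speed(model.stride_frequency)

    speed = 0.0
    supported = False
    if n_c > 0:
        F_n = max(0.0, -g_n) * model.body_mass / n_c + F_ad
        limit = friction_limit(F_n, condition.mu_pyramid)
        demand = model.body_mass * g_tan / n_c + sliding_friction_estimate(
            solver.mu_slide, model.leg_mass, condition.g
        )
        supported = limit > solver.eps_force
        if supported:
            speed = v_sweep * min(1.0, limit / demand)
            F_t = min(demand, limit)
            forces[contact, 0] = F_t
            forces[contact, 1] = F_n
            state.energy += dt * n_c * F_t * v_sweep
    if not supported and condition.is_wall:
        speed = -abs(g_h) / solver.gamma_slip

    # fall bookkeeping (walls only; the model never falls on the ground)
    if condition.is_wall:
        state.airborne = 0.0 if supported else state.airborne + dt
        mask = int((contact * (1 << np.arange(6))).sum())
        peel_rate = model.body_mass * g_tan * model.com_height / solver.j_peel
        if _pattern_ok[mask]:
            state.peel = max(0.0, state.peel - peel_rate * dt)
        else:
            state.peel += peel_rate * dt

    state.position += speed * dt
    state.t = t + dt
    if condition.is_wall and (
        state.peel > solver.theta_peel_max + 1e-9
        or state.airborne > solver.tau_air_max + 1e-9
    ):
        state.fell = True
        state.fall_time = state.t
    return state, contact, forces, speed


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------
@dataclass
class SimulationResult:
    """Trajectory, footfalls, forces and bookkeeping of one simulation."""

    positions: np.ndarray            # (N,) body heading position after each frame, m
    footfall: FootfallDiagram
    contact_forces: np.ndarray       # (N, 6, 2) tangential/normal force, N
    foot_positions: np.ndarray       # (N, 6, 2) body-frame planar foot positions, m
    fell: bool
    fall_time: float | None
    distance: float                  # m, final minus initial heading position
    energy: float                    # J, cumulative foot-power integral
    energy_series: np.ndarray
    dt: float
    duration: float
    condition: SimulationCondition
    gait: GaitPhaseVector
    model: BodyModel = field(default_factory=BodyModel)
    traj: StepTrajectoryParams = field(default_factory=StepTrajectoryParams)

    @property
    def mean_speed(self) -> float:
        """Raw mean forward speed, distance / duration (m/s)."""
        return self.distance / self.duration

    @property
    def forward_speed(self) -> float:
        """Non-negative forward speed used as optimization fitness (m/s)."""
        return max(0.0, self.distance) / self.duration

    def write_outputs(self, out_dir: str | Path, stem: str = "run") -> dict[str, Path]:
        """Serialize trajectory/forces/footfall CSVs and a summary JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        t = np.arange(1, len(self.positions) + 1) * self.dt
        paths = {}
        traj_path = out / f"{stem}_trajectory.csv"
        pd.DataFrame({"t": t, "x": self.positions}).to_csv(traj_path, index=False)
        paths["trajectory"] = traj_path
        rows = []
        for i, leg in enumerate(LEGS):
            rows.append(
                pd.DataFrame(
                    {
                        "t": t,
                        "leg": leg,
                        "F_t": self.contact_forces[:, i, 0],
                        "F_n": self.contact_forces[:, i, 1],
                    }
                )
            )
        forces_path = out / f"{stem}_forces.csv"
        pd.concat(rows).to_csv(forces_path, index=False)
        paths["forces"] = forces_path
        paths["footfall"] = self.footfall.to_csv(out / f"{stem}_footfall.csv")
        summary = {
            "distance_m": self.distance,
            "mean_speed_m_per_s": self.mean_speed,
            "fell": self.fell,
            "fall_time_s": self.fall_time,
            "energy_J": self.energy,
            "condition": self.condition.orientation,
            "adhesion_level": self.condition.adhesion_level,
            "gait_deg": self.gait.as_dict(),
        }
        summary_path = out / f"{stem}_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2))
        paths["summary"] = summary_path
        return paths


def simulate(
    gait: GaitPhaseVector,
    condition: SimulationCondition,
    model: BodyModel | None = None,
    traj: StepTrajectoryParams | None = None,
    solver: SolverParams | None = None,
    duration: float = 0.5,
    dt: float = 1e-3,
) -> SimulationResult:
    """Run the quasi-static template for ``duration`` seconds (deterministic).

    On a fall, the body position freezes at the fall time and ``distance`` is
    the forward distance travelled before falling.
    """
    model = model or BodyModel()
    traj = traj or StepTrajectoryParams()
    solver = solver or SolverParams()
    if dt <= 0 or dt > 1.0 / (4.0 * model.stride_frequency):
        raise ValueError("dt must be positive and at most a quarter cycle")
    n = duration / dt
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration must be an integral number of steps")
    n = int(round(n))
    if duration < 2.0 / model.stride_frequency:
        raise ValueError("duration must cover at least two stride cycles")

    times = np.arange(n) * dt
    contact, offsets = _contact_matrix(gait, model, traj, times)
    n_c = contact.sum(axis=1)
    has_contact = n_c > 0
    g_h, g_l, g_n = gravity_components(condition)
    g_tan = math.hypot(g_h, g_l)
    F_ad = adhesion_force(condition.adhesion_level, model.body_mass, condition.g)
    v_sweep = traj.sweep_speed(model.stride_frequency)

    with np.errstate(divide="ignore", invalid="ignore"):
        F_n = np.where(has_contact, max(0.0, -g_n) * model.body_mass / np.maximum(n_c, 1), 0.0)
    F_n = np.where(has_contact, F_n + F_ad, 0.0)
    limit = condition.mu_pyramid * F_n
    demand = np.where(
        has_contact,
        model.body_mass * g_tan / np.maximum(n_c, 1)
        + solver.mu_slide * model.leg_mass * condition.g,
        0.0,
    )
    supported = has_contact & (limit > solver.eps_force)
    with np.errstate(divide="ignore", invalid="ignore"):
        stick = np.minimum(1.0, np.where(demand > 0, limit / demand, 1.0))
    speed = np.where(supported, v_sweep * stick, 0.0)
    if condition.is_wall:
        speed = np.where(supported, speed, -abs(g_h) / solver.gamma_slip)
    F_t = np.where(supported, np.minimum(demand, limit), 0.0)

    # fall bookkeeping
    fall_frame = n  # index of first frame whose *end* crosses a threshold
    if condition.is_wall:
        # airborne accumulator: consecutive unsupported time, reset on support
        idx = np.arange(n)
        last_sup = np.maximum.accumulate(np.where(supported, idx, -1))
        airborne = (idx - last_sup) * dt
        airborne[supported] = 0.0
        # peel accumulator: +rate while the pattern cannot hold, -rate otherwise,
        # clipped at zero (clipped cumsum via running-minimum identity)
        pattern_ok = _pattern_table(model, solver)
        masks = (contact * (1 << np.arange(6))[None, :]).sum(axis=1)
        bad = ~pattern_ok[masks]
        peel_rate = model.body_mass * g_tan * model.com_height / solver.j_peel
        delta = np.where(bad, peel_rate * dt, -peel_rate * dt)
        s_cum = np.cumsum(delta)
        peel = s_cum - np.minimum(0.0, np.minimum.accumulate(s_cum))
        crossed = (peel > solver.theta_peel_max + 1e-9) | (
            airborne > solver.tau_air_max + 1e-9
        )
        if crossed.any():
            fall_frame = int(np.argmax(crossed))

    fell = fall_frame < n
    if fell:
        speed = speed.copy()
        speed[fall_frame + 1:] = 0.0
        contact = contact.copy()
        contact[fall_frame + 1:, :] = False
        F_t = F_t.copy()
        F_t[fall_frame + 1:] = 0.0
        F_n = F_n.copy()
        F_n[fall_frame + 1:] = 0.0

    positions = np.cumsum(speed * dt)
    energy_steps = np.where(supported, n_c * F_t * v_sweep * dt, 0.0)
    if fell:
        energy_steps = energy_steps.copy()
        energy_steps[fall_frame + 1:] = 0.0
    energy_series = np.cumsum(energy_steps)

    forces = np.zeros((n, 6, 2))
    forces[:, :, 0] = contact * F_t[:, None]
    forces[:, :, 1] = contact * F_n[:, None]
    foot_xy = np.empty((n, 6, 2))
    foot_xy[:, :, 0] = model.feet[None, :, 0] + offsets
    foot_xy[:, :, 1] = model.feet[None, :, 1]

    footfall = FootfallDiagram(
        stance=contact,
        frame_rate=1.0 / dt,
        source="simulated",
        frames_per_cycle=int(round(1.0 / (model.stride_frequency * dt))),
    )
    return SimulationResult(
        positions=positions,
        footfall=footfall,
        contact_forces=forces,
        foot_positions=foot_xy,
        fell=fell,
        fall_time=(fall_frame + 1) * dt if fell else None,
        distance=float(positions[-1]),
        energy=float(energy_series[-1]),
        energy_series=energy_series,
        dt=dt,
        duration=duration,
        condition=condition,
        gait=gait,
        model=model,
        traj=traj,
    )
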