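"""Particle Swarm Optimization over the periodic 5-D gait phase space.

Each particle is a candidate gait: five normalized phases in [0, 1) for legs
(R1, L2, R2, L3, R3), with L1 anchored at phase 0.  The canonical constricted
PSO coefficients are used (inertia w = 0.729, cognitive and social rates
c1 = c2 = 1.49) with per-dimension velocities capped at 0.4 of the parameter
space.  Because phase space is circular (0 = 2*pi), the attraction terms use
the signed shortest periodic displacement and positions wrap modulo 1.

Fitness is the model's forward velocity over 0.5 s of simulated time; if the
model falls during climbing, the forward distance travelled before falling
still counts, which smooths the fitness landscape.  The optimizer reports the
single best gait found over *all* iterations, not the final-iteration best.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .gaits import GaitPhaseVector, signed_phase_delta
from .simulator import (
    BodyModel,
    SimulationCondition,
    SolverParams,
    StepTrajectoryParams,
    simulate,
)

__all__ = [
    "SwarmConfig",
    "Particle",
    "PSOResult",
    "pso_velocity_update",
    "pso_position_update",
    "gait_fitness",
    "run_pso",
    "optimize_gait",
]


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm size, iteration budget and the constricted-PSO coefficients."""

    n_particles: int = 50
    n_iterations: int = 150
    w: float = 0.729
    c1: float = 1.49
    c2: float = 1.49
    v_max: float = 0.4   # per-dimension cap, fraction of parameter space
    dim: int = 5
    topology: str = "global"  # global (star) neighbourhood best

    def __post_init__(self) -> None:
        if not 0.0 < self.w < 1.0:
            raise ValueError("inertia weight must lie in (0, 1)")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("cognitive and social rates must be positive")
        if not 0.0 < self.v_max <= 1.0:
            raise ValueError("v_max must lie in (0, 1]")
        if self.topology != "global":
            raise ValueError("only the global (star) topology is implemented")


@dataclass
class Particle:
    """Position/velocity pair with the particle's personal best."""

    x: np.ndarray
    v: np.ndarray
    best_x: np.ndarray
    best_f: float
    f: float


@dataclass
class PSOResult:
    """All-time best solution plus per-iteration best-so-far history."""

    best_x: np.ndarray
    best_f: float
    history: np.ndarray          # best-so-far fitness after each iteration
    swarm: list[Particle]
    config: SwarmConfig
    seed: int | None = None

    @property
    def best_gait(self) -> GaitPhaseVector:
        return GaitPhaseVector.from_normalized(self.best_x)


def pso_velocity_update(
    v: np.ndarray,
    x: np.ndarray,
    p_best: np.ndarray,
    g_best: np.ndarray,
    r1: float | np.ndarray,
    r2: float | np.ndarray,
    config: SwarmConfig,
) -> np.ndarray:
    """Velocity update with periodic attraction and per-dimension clamping."""
    v = np.asarray(v, float)
    new_v = (
        config.w * v
        + config.c1 * np.asarray(r1) * signed_phase_delta(p_best, x)
        + config.c2 * np.asarray(r2) * signed_phase_delta(g_best, x)
    )
    return np.clip(new_v, -config.v_max, config.v_max)


def pso_position_update(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Periodic position update: wrap each dimension back into [0, 1)."""
    out = (np.asarray(x, float) + np.asarray(v, float)) % 1.0
    # float modulo of a tiny negative rounds to exactly 1.0; keep [0, 1)
    return np.where(out >= 1.0, 0.0, out)


def gait_fitness(
    x: Sequence[float],
    condition: SimulationCondition,
    model: BodyModel | None = None,
    traj: StepTrajectoryParams | None = None,
    solver: SolverParams | None = None,
    duration: float = 0.5,
    dt: float = 1e-3,
) -> float:
    """Forward velocity (m/s) of the gait encoded by normalized phases ``x``.

    Falls contribute their pre-fall forward distance rather than zero.
    """
    gait = GaitPhaseVector.from_normalized(np.asarray(x, float))
    result = simulate(gait, condition, model=model, traj=traj, solver=solver,
                      duration=duration, dt=dt)
    return result.forward_speed


def run_pso(
    objective: Callable[[np.ndarray], float],
    config: SwarmConfig | None = None,
    seed: int | None = None,
) -> PSOResult:
    """Maximize ``objective`` over the periodic unit cube.

    Deterministic for a fixed seed.  Initial positions are uniform in [0, 1)
    and initial velocities uniform in [-v_max, v_max].  Best-so-far fitness is
    monotonically non-decreasing across iterations by construction.
    """
    config = config or SwarmConfig()
    rng = np.random.default_rng(seed)
    swarm: list[Particle] = []
    for _ in range(config.n_particles):
        x = rng.uniform(0.0, 1.0, config.dim)
        v = rng.uniform(-config.v_max, config.v_max, config.dim)
        f = float(objective(x))
        swarm.append(Particle(x=x, v=v, best_x=x.copy(), best_f=f, f=f))

    best = max(swarm, key=lambda p: p.best_f)
    g_best_x, g_best_f = best.best_x.copy(), best.best_f
    history = []
    for _ in range(config.n_iterations):
        for p in swarm:
            r1 = rng.uniform(0.0, 1.0, config.dim)
            r2 = rng.uniform(0.0, 1.0, config.dim)
            p.v = pso_velocity_update(p.v, p.x, p.best_x, g_best_x, r1, r2, config)
            p.x = pso_position_update(p.x, p.v)
            p.f = float(objective(p.x))
            if p.f > p.best_f:
                p.best_f = p.f
                p.best_x = p.x.copy()
        it_best = max(swarm, key=lambda q: q.best_f)
        if it_best.best_f > g_best_f:
            g_best_f = it_best.best_f
            g_best_x = it_best.best_x.copy()
        history.append(g_best_f)
    return PSOResult(
        best_x=g_best_x,
        best_f=g_best_f,
        history=np.asarray(history),
        swarm=swarm,
        config=config,
        seed=seed,
    )


def optimize_gait(
    condition: SimulationCondition,
    config: SwarmConfig | None = None,
    seed: int | None = None,
    model: BodyModel | None = None,
    traj: StepTrajectoryParams | None = None,
    solver: SolverParams | None = None,
    duration: float = 0.5,
    dt: float = 1e-3,
) -> PSOResult:
    """Discover a fast gait for one locomotor condition via PSO."""

    def objective(x: np.ndarray) -> float:
        return gait_fitness(x, condition, model=model, traj=traj, solver=solver,
                            duration=duration, dt=dt)

    return run_pso(objective, config=config, seed=seed)
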