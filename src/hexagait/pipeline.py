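"""Full-study orchestration: conditions x repeated gait optimizations.

The study optimizes locomotor gaits under five conditions — upward, downward
and sideways climbing with adhesion, ground walking with adhesion, and ground
walking without adhesion — repeating the swarm optimization from independent
seeds, then scores every winning gait (speed, class, TCS, stance count, duty
factor, static stability, cost of transport) into one tidy table.

Two profiles are provided: the full-scale profile (50 particles x 150
iterations x 15 experiments per condition) and a desk-scale profile
(20 x 60 x 10) whose stochastic conclusions — climbing enriches tripod
coordination, flat ground without adhesion favours low-TCS bipod gaits —
mirror the full study at a fraction of the cost.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import __version__ as _pkg_version
from .analysis import (
    InsufficientDataError,
    bipod_coordination_strength,
    cost_of_transport,
    duty_factors,
    mean_stance_count,
    static_stability_fraction,
    tcs,
)
from .footfall import LEGS, FootfallDiagram
from .gaits import GaitClassTable, classify_gait, default_class_table
from .optimizer import PSOResult, SwarmConfig, optimize_gait
from .simulator import (
    BodyModel,
    SimulationCondition,
    SolverParams,
    StepTrajectoryParams,
    simulate,
)

__all__ = [
    "CONDITION_NAMES",
    "ExperimentManifest",
    "condition_from_name",
    "run_experiment",
    "run_study",
    "render_gait_diagram",
]

log = logging.getLogger("hexagait")

#: Study conditions: surface orientation plus adhesion level (percent).
CONDITION_NAMES: dict[str, tuple[str, float]] = {
    "wall_up": ("wall_up", 200.0),
    "wall_down": ("wall_down", 200.0),
    "wall_side": ("wall_side", 200.0),
    "ground_adhesion": ("ground", 200.0),
    "ground": ("ground", 0.0),
}

PROFILES: dict[str, dict] = {
    "paper": {"n_particles": 50, "n_iterations": 150, "experiments": 15},
    "desk": {"n_particles": 20, "n_iterations": 60, "experiments": 10},
}


def condition_from_name(name: str, g: float = 9.81, mu_pyramid: float = 4.0) -> SimulationCondition:
    """Build the :class:`SimulationCondition` for a named study condition."""
    key = name.replace("-", "_")
    if key not in CONDITION_NAMES:
        raise ValueError(f"unknown condition {name!r}; choose from {sorted(CONDITION_NAMES)}")
    orientation, adhesion = CONDITION_NAMES[key]
    return SimulationCondition(
        orientation=orientation, adhesion_level=adhesion, mu_pyramid=mu_pyramid, g=g
    )


@dataclass
class ExperimentManifest:
    """Fully determines a study: conditions, repetitions, configs and seeds."""

    conditions: tuple[str, ...] = tuple(CONDITION_NAMES)
    experiments_per_condition: int = 15
    profile: str = "paper"
    base_seed: int = 0
    swarm: SwarmConfig | None = None
    duration: float = 0.5
    dt: float = 1e-3
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {sorted(PROFILES)}")
        prof = PROFILES[self.profile]
        if self.swarm is None:
            self.swarm = SwarmConfig(
                n_particles=prof["n_particles"], n_iterations=prof["n_iterations"]
            )

    @classmethod
    def desk(cls, base_seed: int = 0, conditions: tuple[str, ...] | None = None,
             **kwargs) -> "ExperimentManifest":
        prof = PROFILES["desk"]
        return cls(
            conditions=conditions or tuple(CONDITION_NAMES),
            experiments_per_condition=prof["experiments"],
            profile="desk",
            base_seed=base_seed,
            **kwargs,
        )

    def seeds_for(self, condition: str) -> list[int]:
        """Unique deterministic seeds per (condition, experiment), < 2**31."""
        seeds = []
        for k in range(self.experiments_per_condition):
            digest = hashlib.sha256(
                f"{self.base_seed}:{condition}:{k}".encode()
            ).digest()
            seeds.append(int.from_bytes(digest[:4], "big") % (2**31))
        return seeds

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentManifest":
        raw = yaml.safe_load(Path(path).read_text())
        swarm = SwarmConfig(**raw.pop("swarm")) if "swarm" in raw else None
        raw["conditions"] = tuple(raw.get("conditions", tuple(CONDITION_NAMES)))
        return cls(swarm=swarm, **raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _score_gait(
    result_opt: PSOResult,
    condition_name: str,
    model: BodyModel,
    traj: StepTrajectoryParams,
    solver: SolverParams,
    table: GaitClassTable,
    duration: float,
    dt: float,
) -> dict:
    """Simulate the winning gait and compute the full metric row."""
    gait = result_opt.best_gait
    condition = condition_from_name(condition_name)
    sim = simulate(gait, condition, model=model, traj=traj, solver=solver,
                   duration=duration, dt=dt)
    row: dict = {
        "condition": condition_name,
        "seed": result_opt.seed,
        "speed": result_opt.best_f,
        "fell": sim.fell,
        "gait_deg": json.dumps({leg: round(v, 2) for leg, v in gait.as_dict().items()}),
    }
    row["class"] = classify_gait(gait, sim.footfall, table)
    try:
        row["tcs"] = tcs(sim.footfall)
        row["bipod_coordination"] = bipod_coordination_strength(sim.footfall)
    except InsufficientDataError:
        # fell before three strides: no tripod coordination to speak of
        row["tcs"] = 0.0
        row["bipod_coordination"] = 0.0
    try:
        row["mean_stance_count"] = mean_stance_count(sim.footfall)
        row["duty_factor"] = float(duty_factors(sim.footfall).mean())
    except InsufficientDataError:
        row["mean_stance_count"] = np.nan
        row["duty_factor"] = np.nan
    # stability is a ground concept: retest climbing gaits during ground
    # locomotion, keeping the adhesion level used during optimization
    ground = SimulationCondition(
        orientation="ground",
        adhesion_level=condition.adhesion_level,
        mu_pyramid=condition.mu_pyramid,
        g=condition.g,
    )
    ground_sim = simulate(gait, ground, model=model, traj=traj, solver=solver,
                          duration=duration, dt=dt)
    try:
        row["stability_pct"] = static_stability_fraction(ground_sim, model)
    except InsufficientDataError:
        row["stability_pct"] = np.nan
    try:
        row["cot"] = cost_of_transport(sim)
    except ZeroDivisionError:
        row["cot"] = np.nan
    return row


def run_experiment(
    condition_name: str,
    seed: int,
    swarm: SwarmConfig,
    model: BodyModel | None = None,
    traj: StepTrajectoryParams | None = None,
    solver: SolverParams | None = None,
    table: GaitClassTable | None = None,
    duration: float = 0.5,
    dt: float = 1e-3,
) -> tuple[dict, PSOResult]:
    """One optimization experiment plus the scored metric row."""
    model = model or BodyModel()
    traj = traj or StepTrajectoryParams()
    solver = solver or SolverParams()
    table = table or default_class_table()
    condition = condition_from_name(condition_name)
    opt = optimize_gait(condition, config=swarm, seed=seed, model=model,
                        traj=traj, solver=solver, duration=duration, dt=dt)
    row = _score_gait(opt, condition_name, model, traj, solver, table, duration, dt)
    return row, opt


def run_study(
    manifest: ExperimentManifest,
    model: BodyModel | None = None,
    traj: StepTrajectoryParams | None = None,
    solver: SolverParams | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every (condition, experiment) cell of the manifest.

    Returns the tidy study table (one row per experiment).  Per-run fitness
    histories and the table itself are written under ``manifest.out_dir``
    when set.  Failures are isolated per experiment and logged, never fatal.
    """
    table = default_class_table()
    model = model or BodyModel()
    traj = traj or StepTrajectoryParams()
    solver = solver or SolverParams()
    out_dir = Path(manifest.out_dir) if manifest.out_dir else None
    if out_dir:
        (out_dir / "runs").mkdir(parents=True, exist_ok=True)
    rows = []
    cells = [
        (cond, k, seed)
        for cond in manifest.conditions
        for k, seed in enumerate(manifest.seeds_for(cond))
    ]
    iterator = cells
    if progress:
        from tqdm import tqdm

        iterator = tqdm(cells, desc="study")
    for cond, k, seed in iterator:
        try:
            row, opt = run_experiment(
                cond, seed, manifest.swarm, model=model, traj=traj, solver=solver,
                table=table, duration=manifest.duration, dt=manifest.dt,
            )
            row["experiment"] = k
            rows.append(row)
            log.info(
                "run condition=%s exp=%d seed=%d hash=%s version=%s speed=%.4f class=%s",
                cond, k, seed, manifest.config_hash(), _pkg_version,
                row["speed"], row["class"],
            )
            if out_dir:
                run_record = {
                    "condition": cond,
                    "experiment": k,
                    "seed": seed,
                    "config": asdict(manifest.swarm),
                    "config_hash": manifest.config_hash(),
                    "package_version": _pkg_version,
                    "best_vector_deg": opt.best_gait.as_dict(),
                    "best_fitness": opt.best_f,
                    "fitness_history": list(map(float, opt.history)),
                }
                (out_dir / "runs" / f"{cond}_{k:02d}.json").write_text(
                    json.dumps(run_record, indent=2)
                )
        except Exception:  # noqa: BLE001 - isolate per-experiment failures
            log.exception("experiment failed: condition=%s exp=%d seed=%d", cond, k, seed)
            rows.append({"condition": cond, "experiment": k, "seed": seed})
    df = pd.DataFrame(rows)
    if out_dir:
        df.to_csv(out_dir / "study.csv", index=False)
    return df


def render_gait_diagram(diagram: FootfallDiagram, out: str | Path) -> Path:
    """Render a black/white stance raster with leg labels and a time axis."""
    if diagram.n_frames < 1:
        raise ValueError("empty diagram")
    fig, ax = plt.subplots(figsize=(8, 2.4))
    ax.imshow(
        diagram.stance.T,
        cmap="gray_r",
        aspect="auto",
        interpolation="nearest",
        extent=(0, diagram.duration, len(LEGS) - 0.5, -0.5),
    )
    ax.set_yticks(range(len(LEGS)), labels=list(LEGS))
    ax.set_xlabel("time (s)")
    fig.tight_layout()
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
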