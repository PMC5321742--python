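"""Closed-form physics and the quasi-static locomotion template."""

import numpy as np
import pytest

from hexagait.gaits import BIPOD_B, TRIPOD_A, GaitPhaseVector
from hexagait.simulator import (
    BodyModel,
    SimState,
    SimulationCondition,
    SolverParams,
    StepTrajectoryParams,
    _pattern_table,
    adhesion_force,
    drag_force,
    friction_limit,
    froude_scaled_frequency,
    gravity_components,
    leg_tip_speed,
    prescribed_foot_state,
    servo_velocity,
    simulate,
    sliding_friction_estimate,
    step,
)

ALL_ZERO = GaitPhaseVector((0, 0, 0, 0, 0, 0))


def contact_coverage(gait: GaitPhaseVector, kappa: float) -> tuple[float, int]:
    """Independent oracle: measure of the union of stance windows.

    Each leg occupies the circular interval [phase/360, phase/360 + kappa);
    returns (fraction of the cycle with >= 1 leg down, number of maximal
    covered intervals), computed by exact interval arithmetic.
    """
    events = []
    for p in np.asarray(gait.phases) / 360.0:
        a, b = p, p + kappa
        if b <= 1.0:
            events.append((a, b))
        else:
            events.append((a, 1.0))
            events.append((0.0, b - 1.0))
    events.sort()
    merged = []
    for a, b in events:
        if merged and a <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    # wrap-around merge
    if len(merged) > 1 and merged[0][0] <= 1e-12 and merged[-1][1] >= 1.0 - 1e-12:
        merged[0][0] = merged[-1][0] - 1.0
        merged.pop()
    return sum(b - a for a, b in merged), len(merged)


class TestClosedFormPhysics:
    @pytest.mark.parametrize(
        ("P", "pt", "pc", "vd", "expected"),
        [(10, 0.5, 0.4, 0.5, 0.5), (10, 0.41, 0.4, 5, 0.1), (10, 0.4, 0.5, 5, -1.0)],
    )
    def test_servo_velocity(self, P, pt, pc, vd, expected):
        assert servo_velocity(P, pt, pc, vd) == pytest.approx(expected)

    def test_sliding_friction(self):
        assert sliding_friction_estimate(0.1, 1.42e-7, 9.81) == pytest.approx(1.393e-7, rel=1e-3)
        assert sliding_friction_estimate(0.0, 1.0, 9.81) == 0.0
        assert sliding_friction_estimate(1.0, 1.0, 9.81) == pytest.approx(9.81)

    def test_friction_pyramid_limit(self):
        assert friction_limit(1e-6, 4) == pytest.approx(4e-6)
        assert friction_limit(0.0, 4) == 0.0
        assert friction_limit(2.5e-7, 4) == pytest.approx(1e-6)
        with pytest.raises(ValueError):
            friction_limit(-1e-9, 4)

    def test_adhesion_levels(self):
        # 100% = one body weight (single-foot inverted suspension force)
        assert adhesion_force(100, 8.5e-7) == pytest.approx(8.34e-6, rel=5e-3)
        assert adhesion_force(200, 8.5e-7) == pytest.approx(1.67e-5, rel=5e-3)
        assert adhesion_force(0, 8.5e-7) == 0.0

    def test_drag_single_leg_negligible_vs_friction(self):
        leg_drag = drag_force(1.225, 1.05, 5e-8, leg_tip_speed(20, 0.0005))
        friction = sliding_friction_estimate(0.1, 1.42e-7, 9.81)
        assert leg_drag == pytest.approx(1.27e-10, rel=0.01)
        assert friction / leg_drag > 1e3  # friction dominates by 3 orders

    def test_froude_identity(self):
        assert froude_scaled_frequency(20, 2.5e-3, 2.5e-3) == pytest.approx(20.0)

    def test_gravity_components(self):
        g = 9.81
        assert gravity_components(SimulationCondition("ground")) == (0, 0, -g)
        assert gravity_components(SimulationCondition("wall_up")) == (-g, 0, 0)
        assert gravity_components(SimulationCondition("wall_down")) == (g, 0, 0)
        assert gravity_components(SimulationCondition("wall_side")) == (0, -g, 0)


class TestPrescribedFootState:
    def test_window_start_and_phase_offset(self, model, traj):
        pos, on, speed = prescribed_foot_state("L1", 0.0, TRIPOD_A, traj, model)
        assert on and pos[0] == pytest.approx(model.feet[0][0] + traj.sweep_length / 2)
        _, on_r1, _ = prescribed_foot_state("R1", 0.0, TRIPOD_A, traj, model)
        assert not on_r1  # phase 180 -> cycle position 0.5 >= kappa

    def test_sweep_speed_default(self, model, traj):
        # s * f / kappa = 1 mm * 20 Hz / 0.4
        assert traj.sweep_speed(model.stride_frequency) == pytest.approx(0.05)

    def test_swing_lifts_the_foot(self, model, traj):
        t_mid_swing = (traj.contact_fraction + (1 - traj.contact_fraction) / 2) / 20.0
        pos, on, _ = prescribed_foot_state("L1", t_mid_swing, TRIPOD_A, traj, model)
        assert not on and pos[2] == pytest.approx(traj.swing_clearance, rel=1e-6)


class TestSimulateGround:
    def test_tripod_speed_closed_form(self, ground):
        res = simulate(TRIPOD_A, ground)
        assert not res.fell
        assert res.mean_speed == pytest.approx(0.04, abs=1e-3)

    def test_bipod_faster_full_coverage(self, ground):
        res = simulate(BIPOD_B, ground)
        assert res.mean_speed == pytest.approx(0.05, abs=1e-3)

    def test_synchronous_gait_single_pulse(self, ground, traj):
        res = simulate(ALL_ZERO, ground)
        assert res.mean_speed == pytest.approx(0.05 * traj.contact_fraction, abs=1e-3)

    def test_random_gaits_match_coverage_oracle(self, ground, traj, random_gaits):
        v_sweep = 0.05
        for gait in random_gaits(100):
            res = simulate(gait, ground)
            coverage, n_intervals = contact_coverage(gait, traj.contact_fraction)
            tol = v_sweep * 2 * n_intervals * (res.dt * 20.0)  # one frame per boundary
            assert res.mean_speed == pytest.approx(v_sweep * coverage, abs=tol)
            assert not res.fell

    def test_never_falls_on_ground(self, random_gaits):
        cond = SimulationCondition("ground", adhesion_level=0.0)
        for gait in random_gaits(10):
            assert not simulate(gait, cond).fell


class TestSimulateWall:
    def test_tripod_climbs_with_adhesion(self, wall_up):
        res = simulate(TRIPOD_A, wall_up)
        assert not res.fell and res.distance > 0

    def test_bipod_peels_off(self, wall_up):
        res = simulate(BIPOD_B, wall_up)
        assert res.fell and res.fall_time < 0.1

    def test_no_adhesion_no_grip(self):
        res = simulate(TRIPOD_A, SimulationCondition("wall_up", adhesion_level=0.0))
        assert res.fell and res.distance <= 0

    def test_adhesion_monotonically_helps(self, random_gaits):
        for gait in random_gaits(5):
            distances = [
                simulate(gait, SimulationCondition("wall_up", adhesion_level=a)).distance
                for a in (0, 100, 200, 400)
            ]
            assert all(d1 <= d2 + 1e-12 for d1, d2 in zip(distances, distances[1:]))


class TestBookkeeping:
    def test_determinism(self, wall_up, random_gaits):
        (gait,) = random_gaits(1)
        a, b = simulate(gait, wall_up), simulate(gait, wall_up)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.footfall.stance, b.footfall.stance)
        assert a.energy == b.energy

    def test_frame_count_and_energy_ledger(self, ground):
        res = simulate(TRIPOD_A, ground)
        assert res.footfall.n_frames * res.dt == pytest.approx(res.duration)
        assert res.energy >= 0
        assert np.all(np.diff(res.energy_series) >= -1e-18)
        assert res.distance == pytest.approx(res.positions[-1])

    def test_undersampled_dt_rejected(self, ground):
        with pytest.raises(ValueError):
            simulate(TRIPOD_A, ground, dt=0.02)  # > quarter cycle at 20 Hz

    def test_step_matches_vectorized_simulate(self, model, traj, solver, random_gaits):
        """The scalar step() reference reproduces simulate() bit-for-bit."""
        pattern = _pattern_table(model, solver)
        conditions = [
            SimulationCondition("ground", 0.0),
            SimulationCondition("wall_up", 200.0),
            SimulationCondition("wall_side", 200.0),
        ]
        for gait, cond in zip(random_gaits(3), conditions):
            res = simulate(gait, cond, duration=0.5, dt=1e-3)
            state = SimState()
            positions = []
            for k in range(500):
                state, _, _, _ = step(
                    state, k * 1e-3, gait, cond, model, traj, solver, 1e-3, pattern
                )
                positions.append(state.position)
            assert np.allclose(positions, res.positions)
            assert state.fell == res.fell
            assert state.energy == pytest.approx(res.energy)

    def test_write_outputs(self, tmp_path, ground):
        res = simulate(TRIPOD_A, ground)
        paths = res.write_outputs(tmp_path)
        assert set(paths) == {"trajectory", "forces", "footfall", "summary"}
        assert all(p.exists() for p in paths.values())


class TestModelValidation:
    def test_mirror_symmetry_enforced(self):
        feet = list(BodyModel().foot_home_positions)
        feet[1] = (feet[1][0], feet[1][1] + 1e-4)
        with pytest.raises(ValueError):
            BodyModel(foot_home_positions=tuple(feet))

    def test_positive_masses(self):
        with pytest.raises(ValueError):
            BodyModel(body_mass=0.0)

    def test_unknown_orientation(self):
        with pytest.raises(ValueError):
            SimulationCondition("ceiling")
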