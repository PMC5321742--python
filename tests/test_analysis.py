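"""Footfall metrics: TCS, bipod coordination, stability, COT, friction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexagait.analysis import (
    EnergyAccounting,
    InsufficientDataError,
    bipod_coordination_strength,
    classify_fly_trial,
    cost_of_transport,
    duty_factors,
    mean_stance_count,
    point_in_convex_support,
    static_friction_coefficient,
    static_stability_fraction,
    tcs,
)
from hexagait.footfall import FootfallDiagram
from hexagait.gaits import BIPOD_B, TRIPOD_A, GaitPhaseVector, ideal_footfall
from hexagait.simulator import SimulationCondition, simulate


def tripod_diagram(cycles=6, fpc=100):
    return ideal_footfall(TRIPOD_A, 0.5, cycles, fpc)


def bipod_diagram(cycles=6, fpc=99):
    return ideal_footfall(BIPOD_B, 1 / 3, cycles, fpc)


class TestTCS:
    def test_ideal_tripod_is_pure(self):
        assert tcs(tripod_diagram()) == 1.0

    def test_ideal_bipod_never_in_tripod_stance(self):
        assert tcs(bipod_diagram()) == 0.0

    def test_all_stance_is_not_a_tripod(self):
        d = FootfallDiagram(np.ones((400, 6), bool), 100.0, frames_per_cycle=100)
        # all six legs down is not "only" a tripod set; but an all-stance
        # trace has no R1 onsets at all -> insufficient for windowing
        with pytest.raises(InsufficientDataError):
            tcs(d)

    def test_superset_stance_does_not_count(self):
        d = tripod_diagram()
        stance = d.stance.copy()
        stance[:, :] |= True  # every leg always down
        full = FootfallDiagram(stance, d.frame_rate, frames_per_cycle=100)
        stance2 = full.stance.copy()
        stance2[::100, 1] = False  # rare R1 lifts create onsets
        with_onsets = FootfallDiagram(stance2, d.frame_rate, frames_per_cycle=100)
        assert tcs(with_onsets) == 0.0

    def test_too_few_cycles_rejected(self):
        with pytest.raises(InsufficientDataError):
            tcs(tripod_diagram(cycles=2))


class TestBipodCoordination:
    def test_ideal_bipod_fully_synchronized(self):
        assert bipod_coordination_strength(bipod_diagram()) == 1.0

    def test_ideal_tripod_pairs_antiphase(self):
        assert bipod_coordination_strength(tripod_diagram()) == 0.0

    def test_metric_separation_is_complete(self):
        """TCS and bipod coordination fully separate the two ideal gaits."""
        t, b = tripod_diagram(), bipod_diagram()
        assert (tcs(t), bipod_coordination_strength(t)) == (1.0, 0.0)
        assert (tcs(b), bipod_coordination_strength(b)) == (0.0, 1.0)


class TestStanceAndDuty:
    @pytest.mark.parametrize(
        ("vector", "duty", "expected_count"),
        [
            (TRIPOD_A, 0.5, 3.0),
            (BIPOD_B, 1 / 3, 2.0),
            (GaitPhaseVector((0, 180, 60, 240, 120, 300)), 5 / 6, 5.0),  # wave
        ],
    )
    def test_mean_stance_count(self, vector, duty, expected_count):
        d = ideal_footfall(vector, duty, 7, 120)
        assert mean_stance_count(d) == pytest.approx(expected_count, abs=0.05)

    def test_duty_factors_per_leg(self):
        assert np.allclose(duty_factors(tripod_diagram(7)), 0.5)
        assert np.allclose(duty_factors(bipod_diagram(7, 120)), 1 / 3, atol=0.01)

    def test_running_gaits_have_low_duty(self):
        assert (duty_factors(bipod_diagram(7, 120)) < 0.5).all()

    def test_short_diagram_rejected(self):
        with pytest.raises(InsufficientDataError):
            mean_stance_count(tripod_diagram(cycles=3))


class TestSupportPolygon:
    def test_square_contains_centre(self):
        feet = [(1, 1), (1, -1), (-1, 1), (-1, -1)]
        assert point_in_convex_support((0, 0), feet)

    def test_point_outside_triangle(self):
        assert not point_in_convex_support((2, 0), [(0, 0), (1, 0), (0, 1)])

    def test_degenerate_supports_are_unstable(self):
        assert not point_in_convex_support((0, 0), [(1, 1), (-1, -1)])
        assert not point_in_convex_support((0, 0), [(0, 1), (0, 0), (0, -1)])
        assert not point_in_convex_support((0, 0), [])

    @given(data=st.data())
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_agrees_with_half_plane_oracle(self, data):
        """Cross-check shapely hull containment against a brute-force test.

        Integer coordinates keep both routes exact, including degenerate
        (collinear) foot configurations.
        """
        coord = st.integers(-5, 5)
        pts = data.draw(
            st.lists(st.tuples(coord, coord), min_size=3, max_size=6)
        )
        point = data.draw(st.tuples(coord, coord))
        got = point_in_convex_support(point, pts)

        def cross(o, a, b):
            return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

        degenerate = all(
            cross(pts[i], pts[j], pts[k]) == 0
            for i in range(len(pts))
            for j in range(len(pts))
            for k in range(len(pts))
        )
        if degenerate:
            assert got is False
            return
        # p lies outside iff some directed point-pair line has every foot on
        # one side and p strictly on the other (a separating half-plane)
        inside = True
        for i in range(len(pts)):
            for j in range(len(pts)):
                if pts[i] == pts[j]:
                    continue
                sides = [cross(pts[i], pts[j], q) for q in pts]
                if all(s <= 0 for s in sides) and cross(pts[i], pts[j], point) > 0:
                    inside = False
        assert got == inside


class TestStaticStability:
    def test_tripod_ground_run_mostly_stable(self):
        res = simulate(TRIPOD_A, SimulationCondition("ground"))
        # contact fraction 0.4 -> support triangles cover 80% of each cycle
        assert static_stability_fraction(res) == pytest.approx(80.0, abs=2.0)

    def test_bipod_ground_run_mostly_unstable(self):
        res = simulate(BIPOD_B, SimulationCondition("ground"))
        tripod = simulate(TRIPOD_A, SimulationCondition("ground"))
        assert static_stability_fraction(res) < 0.5 * static_stability_fraction(tripod)


class TestCostOfTransport:
    def test_definition(self):
        acct = EnergyAccounting(energy=8.5e-7 * 9.81 * 0.02, mass=8.5e-7, distance=0.02)
        assert cost_of_transport(acct) == pytest.approx(1.0)
        assert cost_of_transport(
            EnergyAccounting(energy=0.0, mass=1.0, distance=1.0)
        ) == 0.0

    def test_zero_distance_signalled(self):
        with pytest.raises(ZeroDivisionError):
            cost_of_transport(EnergyAccounting(energy=1.0, mass=1.0, distance=0.0))

    def test_bipod_cheaper_than_tripod_on_ground(self):
        ground = SimulationCondition("ground")
        cot_tripod = cost_of_transport(simulate(TRIPOD_A, ground))
        cot_bipod = cost_of_transport(simulate(BIPOD_B, ground))
        assert cot_bipod < cot_tripod


class TestStaticFriction:
    @pytest.mark.parametrize(("theta", "mu"), [(45, 1.0), (0, 0.0), (40, 0.839)])
    def test_tilt_angle_to_mu(self, theta, mu):
        assert static_friction_coefficient(theta) == pytest.approx(mu, abs=1e-3)

    def test_vertical_tilt_rejected(self):
        with pytest.raises(ValueError):
            static_friction_coefficient(90)


def test_classify_fly_trial_separates_families():
    assert classify_fly_trial(tripod_diagram()) == "tripod"
    assert classify_fly_trial(bipod_diagram()) == "bipod"
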