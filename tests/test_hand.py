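"""Digit kinematics, moment arms (tendon excursion) and chain dynamics."""

import numpy as np
import pytest

from jfisim.hand import (
    DigitGeometry,
    HandModel,
    RevoluteJoint,
    RoutingPath,
    ViaPoint,
    joint_torques,
    mass_matrix,
    moment_arm,
    moment_arm_topology,
    passive_torques,
    path_length,
    step_dynamics,
)
from jfisim.synthetic import gen_hand_fixture


@pytest.fixture(scope="module")
def digit():
    return DigitGeometry(3, (0.050, 0.030, 0.022))


@pytest.fixture(scope="module")
def joints():
    return tuple(RevoluteJoint() for _ in range(3))


def pin_wrap_path(r=0.005, name="pin", palmar=True):
    """Two via points straddling the MCP joint at perpendicular distance r;
    at q = 0 the chord is tangent to the radius-r pulley circle."""
    y = -r if palmar else r
    return RoutingPath(
        name,
        (ViaPoint(0, (0.07 - 0.02, y), palmar), ViaPoint(1, (0.02, y), palmar)),
    )


def chord_arm_oracle(r, a, b, q, palmar=True):
    """Analytic moment arm of a straight chord about the MCP joint.

    The arm of a straight-line muscle segment equals the signed
    perpendicular distance from the joint center to the chord: point A =
    (-a, -r) fixed, point B = local (b, -r) rotated by the flexion angle
    q (clockwise).  Flexor (palmar) chords give positive arms.
    """
    y = -r if palmar else r
    A = np.array([-a, y])
    c, s = np.cos(q), np.sin(q)
    B = np.array([[c, s], [-s, c]]) @ np.array([b, y])
    d = B - A
    return float(np.cross(d, -A)) / np.linalg.norm(d)


class TestPathLength:
    def test_rigid_segment_is_angle_independent(self, digit):
        p = RoutingPath("seg", (ViaPoint(1, (0.005, -0.004)), ViaPoint(1, (0.045, -0.004))))
        for q in (np.zeros(3), np.array([0.5, 0.8, 0.3])):
            assert path_length(digit, p, q) == pytest.approx(0.040)

    def test_collinear_points_sum_straight_distances(self, digit):
        p = RoutingPath(
            "col",
            (ViaPoint(0, (0.05, -0.003)), ViaPoint(1, (0.01, -0.003)),
             ViaPoint(1, (0.04, -0.003))),
        )
        assert path_length(digit, p, np.zeros(3)) == pytest.approx(0.02 + 0.01 + 0.03)

    def test_flexion_shortens_palmar_path(self, digit):
        """Small flexion shortens a palmar path by about r * dq."""
        r, dq = 0.005, 1e-3
        p = pin_wrap_path(r)
        l0 = path_length(digit, p, np.zeros(3))
        l1 = path_length(digit, p, np.array([dq, 0.0, 0.0]))
        assert (l0 - l1) / dq == pytest.approx(r, rel=1e-3)

    def test_coincident_points_raise(self, digit):
        p = RoutingPath("dup", (ViaPoint(1, (0.01, -0.004)), ViaPoint(1, (0.01, -0.004))))
        with pytest.raises(ValueError, match="coincident"):
            path_length(digit, p, np.zeros(3))


class TestMomentArm:
    def test_pin_wrap_matches_analytic_pulley(self, digit):
        """Tendon-excursion arms agree with the analytic chord-distance
        oracle to < 1e-6 m across 0-90 degrees; at q = 0 the arm equals
        the pulley radius r."""
        r, a, b = 0.005, 0.02, 0.02
        p = pin_wrap_path(r)
        assert moment_arm(digit, p, np.zeros(3), 0) == pytest.approx(r, abs=1e-6)
        for ang in np.deg2rad(np.linspace(0, 90, 10)):
            arm = moment_arm(digit, p, np.array([ang, 0.0, 0.0]), 0)
            assert arm == pytest.approx(chord_arm_oracle(r, a, b, ang), abs=1e-6)

    def test_dorsal_mirror_flips_sign(self, digit):
        """Mirroring the path to the dorsal side flips the arm's sign."""
        r, a, b = 0.005, 0.02, 0.02
        p = pin_wrap_path(r, palmar=False)
        assert moment_arm(digit, p, np.zeros(3), 0) == pytest.approx(-r, abs=1e-6)
        for ang in np.deg2rad((20.0, 55.0)):
            arm = moment_arm(digit, p, np.array([ang, 0.0, 0.0]), 0)
            oracle = chord_arm_oracle(r, a, b, ang, palmar=False)
            assert arm == pytest.approx(oracle, abs=1e-6)

    def test_not_crossing_joint_warns_and_returns_zero(self, digit):
        p = RoutingPath("seg", (ViaPoint(1, (0.005, -0.004)), ViaPoint(1, (0.045, -0.004))))
        with pytest.warns(UserWarning):
            assert moment_arm(digit, p, np.zeros(3), 2) == 0.0

    def test_virtual_work_consistency(self):
        """F * r_j equals the work rate -F * dL/dq_j by construction; check
        against an independent fine finite difference of the path length."""
        model, _ = gen_hand_fixture()
        d = model.digits[3]
        p = model.paths[(3, "FDP")]
        q = np.array([0.3, 0.5, 0.2])
        F = 37.0
        for j in range(3):
            arm = moment_arm(d, p, q, j)
            h = 1e-7
            qp, qm = q.copy(), q.copy()
            qp[j] += h
            qm[j] -= h
            dW = -F * (path_length(d, p, qp) - path_length(d, p, qm)) / (2 * h)
            assert F * arm == pytest.approx(dW, rel=1e-6)

    def test_excursion_integral_equals_path_change(self):
        """Integral of r_j over a flexion ramp equals the path-length change
        (flexors lengthen their path under extension)."""
        model, _ = gen_hand_fixture()
        d, p = model.digits[2], model.paths[(2, "FDP")]
        angs = np.linspace(0.0, 1.2, 4001)
        arms = []
        for a in angs:
            arms.append(moment_arm(d, p, np.array([0.0, a, 0.0]), 1))
        excursion = np.trapezoid(arms, angs)
        l0 = path_length(d, p, np.array([0.0, angs[0], 0.0]))
        l1 = path_length(d, p, np.array([0.0, angs[-1], 0.0]))
        assert excursion == pytest.approx(l0 - l1, abs=1e-8)


class TestTopology:
    def test_twenty_flexor_curves(self):
        """FDP over 3 joints x digits 2-5 plus FDS over 2 joints x digits 2-5
        yields exactly 20 moment-arm curves."""
        model, _ = gen_hand_fixture()
        curves = moment_arm_topology(model)
        assert len(curves) == 20
        assert sum(1 for c in curves if c[0] == "FDP") == 12
        assert sum(1 for c in curves if c[0] == "FDS") == 8
        assert {c[2] for c in curves} == {2, 3, 4, 5}


class TestJointTorques:
    def test_zero_forces_at_rest_give_zero_torque(self):
        model, _ = gen_hand_fixture()
        tau = joint_torques(model, 3, np.zeros(3), {"FDP": 0.0, "FDS": 0.0, "EXT": 0.0})
        assert np.allclose(tau, 0.0)

    def test_single_force_contributes_r_times_f(self):
        model, _ = gen_hand_fixture()
        q = np.array([0.2, 0.4, 0.1])
        F = 12.5
        tau = joint_torques(model, 3, q, {"FDP": F})
        tau0 = joint_torques(model, 3, q, {"FDP": 0.0})
        d, p = model.digits[3], model.paths[(3, "FDP")]
        for j in range(3):
            assert tau[j] - tau0[j] == pytest.approx(moment_arm(d, p, q, j) * F)

    def test_rom_penalty_restores_into_range(self, digit, joints):
        q_over = np.array([np.deg2rad(100.0), 0.0, 0.0])  # beyond MCP 90 deg
        tau = passive_torques(joints, q_over, np.zeros(3))
        assert tau[0] < 0  # extension torque pushing back below the limit
        q_under = np.array([-0.1, 0.0, 0.0])
        tau = passive_torques(joints, q_under, np.zeros(3))
        assert tau[0] > 0

    def test_negative_force_rejected(self):
        model, _ = gen_hand_fixture()
        with pytest.raises(ValueError):
            joint_torques(model, 3, np.zeros(3), {"FDP": -1.0})


class TestDynamics:
    def test_equilibrium_is_stationary(self, digit, joints):
        q, qdot = np.zeros(3), np.zeros(3)
        q2, qd2 = step_dynamics(digit, joints, q, qdot, np.zeros(3), 2e-5)
        assert np.allclose(q2, 0.0) and np.allclose(qd2, 0.0)

    def test_constant_torque_flexes_until_limit(self, digit, joints):
        """A constant flexion torque drives monotone flexion; the ROM penalty
        eventually balances it."""
        q, qdot = np.zeros(3), np.zeros(3)
        tau = np.array([0.05, 0.05, 0.05])
        prev_mcp, increased = q[0], True
        for k in range(int(0.2 / 2e-5)):
            q, qdot = step_dynamics(digit, joints, q, qdot, tau, 2e-5)
        assert np.all(q > 0)
        rom_hi = np.array([j.rom[1] for j in joints])
        assert np.all(q < rom_hi + 0.1)  # held near/below the limits
        assert np.all(np.isfinite(qdot))

    def test_dt_convergence(self, digit, joints):
        """Halving dt changes the angles after a 100 ms forced motion by
        < 1e-4 rad."""
        tau = np.array([0.02, 0.01, 0.005])

        def run(dt):
            q, qdot = np.zeros(3), np.zeros(3)
            for _ in range(int(round(0.1 / dt))):
                q, qdot = step_dynamics(digit, joints, q, qdot, tau, dt)
            return q

        assert np.abs(run(2e-5) - run(1e-5)).max() < 1e-4

    def test_passive_motion_stays_bounded(self, digit, joints):
        q = np.array([0.4, 0.3, 0.2])
        qdot = np.array([2.0, -1.0, 1.0])
        e0 = qdot @ mass_matrix(digit, q) @ qdot
        for _ in range(int(0.2 / 2e-5)):
            q, qdot = step_dynamics(digit, joints, q, qdot, np.zeros(3), 2e-5)
        assert np.all(np.isfinite(q))
        e1 = qdot @ mass_matrix(digit, q) @ qdot
        assert e1 < 10 * e0 + 1e-6  # damped passive motion does not blow up

    def test_dt_above_limit_rejected(self, digit, joints):
        with pytest.raises(ValueError):
            step_dynamics(digit, joints, np.zeros(3), np.zeros(3), np.zeros(3), 1e-3)
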