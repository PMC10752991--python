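"""Contact model, engine internals and short grip/retraction runs."""

import numpy as np
import pytest

from jfisim.loadcase import (
    ContactParams,
    LoadCaseConfig,
    RodConfig,
    _Engine,
    _rod_state,
    activation_effectiveness,
    contact_force,
    run_load_case,
)
from jfisim.mtu import MTUState, contraction_rate
from jfisim.synthetic import gen_hand_fixture


@pytest.fixture(scope="module")
def hand():
    return gen_hand_fixture()


ROD = RodConfig(center=(0.0, 0.0))
CP = ContactParams()
R_EFF = ROD.diameter / 2 + CP.skin_pad  # 15 mm


class TestContactForce:
    def test_separation_gives_zero(self):
        f = contact_force(ROD, (0.05, 0.0), CP)
        assert np.allclose(f, 0.0)

    def test_static_penetration_penalty(self):
        delta = 0.002
        f = contact_force(ROD, (R_EFF - delta, 0.0), CP)
        assert f[0] == pytest.approx(CP.penalty_stiffness * delta)
        assert f[1] == pytest.approx(0.0)

    def test_normal_damping_adds_on_approach(self):
        delta = 0.002
        f = contact_force(ROD, (R_EFF - delta, 0.0), CP, rel_velocity=(-0.1, 0.0))
        assert f[0] == pytest.approx(CP.penalty_stiffness * delta + CP.penalty_damping * 0.1)

    def test_dynamic_friction_at_sliding(self):
        """Sliding at 0.1 m/s: tangential force magnitude = mu_dynamic * N."""
        delta = 0.0005  # N = 10 N, below the viscous cap at 0.1 m/s
        f = contact_force(ROD, (R_EFF - delta, 0.0), CP, rel_velocity=(0.0, 0.1))
        n = CP.penalty_stiffness * delta
        assert abs(f[1]) == pytest.approx(0.3 * n, rel=1e-6)
        assert f[1] < 0  # opposes the sliding direction

    def test_friction_never_exceeds_static_cone(self):
        for v in (1e-4, 1e-3, 0.01, 0.1, 1.0):
            f = contact_force(ROD, (R_EFF - 0.001, 0.0), CP, rel_velocity=(0.0, v))
            n = f[0]
            assert abs(f[1]) <= CP.mu_static * n + 1e-9

    def test_non_finite_point_rejected(self):
        with pytest.raises(ValueError):
            contact_force(ROD, (np.nan, 0.0), CP)


class TestRodKinematics:
    def test_static_before_retraction(self):
        cfg = LoadCaseConfig()
        c, v = _rod_state(RodConfig(), cfg, 0.05)
        assert np.allclose(c, RodConfig().center) and np.allclose(v, 0.0)

    def test_ramp_and_plateau_velocity(self):
        rod, cfg = RodConfig(), LoadCaseConfig()
        _, v_mid = _rod_state(rod, cfg, cfg.t_R + 0.5 * rod.velocity_ramp_time)
        assert np.linalg.norm(v_mid) == pytest.approx(rod.retraction_velocity / 2)
        _, v = _rod_state(rod, cfg, cfg.t_R + 0.01)
        assert np.linalg.norm(v) == pytest.approx(11.615)

    def test_no_retraction_flag(self):
        cfg = LoadCaseConfig(retract=False)
        c, v = _rod_state(RodConfig(), cfg, 0.19)
        assert np.allclose(v, 0.0) and np.allclose(c, RodConfig().center)


class TestEngineSolver:
    def test_vectorized_vce_matches_brentq(self, hand):
        """The engine's vectorized contraction solver agrees with the
        bracketed scalar root find on random strand states."""
        model, strands = hand
        eng = _Engine(model, strands)
        rng = np.random.default_rng(2)
        a = rng.uniform(0.01, 1.0, eng.S)
        l_ce = eng.l_opt * rng.uniform(0.75, 1.15, eng.S)
        l_see = eng.l_see0 * rng.uniform(0.99, 1.025, eng.S)
        v_mtu = rng.uniform(-0.2, 0.2, eng.S)
        v = eng.solve_vce(a, l_ce, l_see, v_mtu, np.zeros(eng.S))
        for i, s in enumerate(strands):
            st = MTUState(a=a[i], l_ce=l_ce[i], l_mtu=l_ce[i] + l_see[i])
            v_ref = contraction_rate(s.params, st, v_mtu[i])
            assert v[i] == pytest.approx(v_ref, abs=1e-7)

    def test_path_lengths_match_public_api(self, hand):
        from jfisim.hand import path_length

        model, strands = hand
        eng = _Engine(model, strands)
        q = np.array([[0.1, 0.2, 0.05]] * 4)
        lengths, _ = eng.muscle_geometry(q)
        for i, d in enumerate(eng.digit_ids):
            for mi, m in enumerate(eng.muscles):
                ref = path_length(model.digits[d], model.paths[(d, m)], q[i])
                assert lengths[i, mi] == pytest.approx(ref, abs=1e-12)


class TestShortRuns:
    CFG = LoadCaseConfig(activation=0.8, t_R=0.012, t_end=0.02, record_stride=10)

    def test_determinism_bit_exact(self, hand):
        model, strands = hand
        contact = ContactParams(tie_activation_time=0.008)
        r1 = run_load_case(model, strands, self.CFG, contact=contact)
        r2 = run_load_case(model, strands, self.CFG, contact=contact)
        np.testing.assert_array_equal(r1.f_mtu, r2.f_mtu)
        np.testing.assert_array_equal(r1.q, r2.q)
        np.testing.assert_array_equal(r1.eps_see, r2.eps_see)

    def test_flexors_activate_and_flex(self, hand):
        model, strands = hand
        contact = ContactParams(tie_activation_time=0.008)
        res = run_load_case(model, strands, self.CFG, contact=contact)
        flex = [i for i, s in enumerate(strands) if s.muscle in ("FDP", "FDS")]
        ext = [i for i, s in enumerate(strands) if s.muscle == "EXT"]
        expected = 0.005 + (0.8 - 0.005) * (1 - np.exp(-self.CFG.t_end / 0.01))
        assert res.activation[-1, flex].min() == pytest.approx(expected, rel=1e-3)
        assert res.activation[-1, ext].max() <= 0.0051
        assert res.q[-1].mean() > res.q[0].mean()  # net flexion
        assert np.all(res.f_mtu >= 0)

    def test_effectiveness_arithmetic(self, hand):
        model, strands = hand
        contact = ContactParams(tie_activation_time=0.008)
        res = run_load_case(model, strands, self.CFG, contact=contact)
        eff = activation_effectiveness(res, strands)
        sel = res.time <= self.CFG.t_R
        flex = [i for i, s in enumerate(strands) if s.muscle in ("FDP", "FDS")]
        peaks = res.f_mtu[sel][:, flex].max(axis=0)
        fmax = np.array([strands[i].params.Fmax for i in flex])
        assert eff.F_bar_mtu == pytest.approx(peaks.mean())
        assert eff.eta_a == pytest.approx(100 * peaks.mean() / fmax.mean())

    def test_effectiveness_synthetic_fixture_values(self):
        """Strand peak mean 956 N against mean Fmax 1000 N gives 95.6 %."""
        from jfisim.loadcase import EffectivenessResult

        eff = EffectivenessResult(1.0, 956.0, 1000.0, 100 * 956 / 1000, 1.3)
        assert eff.eta_a == pytest.approx(95.6)

    def test_grip_failure_warning_without_activation(self, hand):
        """With no flexor drive and a rod far away the hand never grips."""
        model, strands = hand
        cfg = LoadCaseConfig(activation=0.0, t_R=0.012, t_end=0.02,
                             record_stride=10)
        rod = RodConfig(center=(0.2, -0.2))
        with pytest.warns(UserWarning, match="grip failure"):
            res = run_load_case(model, strands, cfg, rod=rod)
        assert res.flags["grip_at_tR"] is False

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LoadCaseConfig(activation=1.5)
        with pytest.raises(ValueError):
            LoadCaseConfig(t_R=0.3, t_end=0.2)
        with pytest.raises(ValueError):
            LoadCaseConfig(record_stride=100)  # sampling below 1 kHz
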