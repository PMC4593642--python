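"""Motor law, focal-complex kinetics/geometry and the phase machine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filosim.filopodium import (
    FiloState,
    FocalComplex,
    advance_state,
    am_forces,
    am_update_and_forces,
    anchor_geometry,
    bell_koff,
    binding_probability,
    candidate_anchor,
    fc_force,
    make_filopodium,
    mean_speed,
    myosin_velocity,
    protrusion_force,
    release_fc,
    sample_bond_formation,
    sample_bond_rupture,
)
from filosim.config import MotorBindingConfig
from filosim.io import make_single_fiber_network, network_from_arrays

_MOTOR = MotorBindingConfig()


class TestMotorLaw:
    def test_unloaded_sliding_rate_is_10_nm_s(self, motor):
        assert myosin_velocity(0.0, motor) == pytest.approx(0.010, abs=0)

    def test_stall(self, motor):
        assert myosin_velocity(motor.f_stall_pn, motor) == 0.0
        assert myosin_velocity(2 * motor.f_stall_pn, motor) == 0.0

    def test_half_stall_load(self, motor):
        # v = 10·(1000−500)/(1000+0.1·500) nm/s = 100/21 nm/s
        assert myosin_velocity(500.0, motor) == pytest.approx(
            0.01 * 500 / 1050, rel=1e-12)
        assert myosin_velocity(500.0, motor) * 1e3 == pytest.approx(100 / 21, rel=1e-12)

    def test_negative_load_rejected(self, motor):
        with pytest.raises(ValueError):
            myosin_velocity(-1.0, motor)

    @settings(deadline=None, max_examples=60)
    @given(st.tuples(st.floats(0.0, 999.0), st.floats(0.0, 999.0)))
    def test_strictly_decreasing_below_stall(self, loads):
        motor = _MOTOR
        f1, f2 = sorted(loads)
        if f2 - f1 > 1e-9:
            assert myosin_velocity(f2, motor) < myosin_velocity(f1, motor)

    def test_monotone_decreasing(self, motor):
        loads = np.linspace(0, motor.f_stall_pn, 200)
        v = np.array([myosin_velocity(f, motor) for f in loads])
        assert np.all(np.diff(v) < 0)


class TestBellKinetics:
    def test_unstressed_dissociation_rate(self, motor):
        assert bell_koff(0.0, motor) == motor.k_off0 == 1.0

    def test_exponent_unity_at_characteristic_force(self, motor):
        # per-bond force k_bT/x_b makes the Bell exponent exactly one
        ext = motor.kt_pn_um / (motor.x_b_um * motor.kappa_lr_pn_um)
        assert bell_koff(ext, motor) == pytest.approx(math.e, rel=1e-12)

    def test_compression_does_not_accelerate_rupture(self, motor):
        assert bell_koff(-0.1, motor) == motor.k_off0

    def test_binding_probability_limits(self, motor):
        assert binding_probability(300, 1e-9, motor) < 1e-6
        assert binding_probability(0, 1.0, motor) == 0.0
        with pytest.raises(ValueError):
            binding_probability(300, 0.0, motor)

    def test_binding_probability_value(self, motor):
        # 300 free ligands, k_f = 1, Δt = 1 ms -> p = 1 − e^{−0.3}
        assert binding_probability(300, 1e-3, motor) == pytest.approx(
            1 - math.exp(-0.3), rel=1e-12)


class TestBondSampling:
    def _fresh_fc(self, net):
        return FocalComplex(seg_id=0, chain_id=0, s=0.5, ligand_node=0,
                            L_b=0.03, n_R=np.array([1.0, 0, 0]))

    def test_empirical_binding_fraction_matches_analytic(self, motor):
        # aggregate over many fresh complexes: binomial with p = 1 − e^{−0.3}
        net = make_single_fiber_network(ligand_capacity=10**9)
        rng = np.random.default_rng(5)
        trials, receptors = 1000, motor.n_receptors
        added = 0
        for _ in range(trials):
            fc = self._fresh_fc(net)
            p = binding_probability(300, 1e-3, motor)
            free = max(receptors - fc.n_b, 0)
            added += int(rng.binomial(free, p))
        n = trials * receptors
        p = 1 - math.exp(-0.3)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(added / n - p) < 3 * se

    def test_bond_count_conservation(self, motor):
        net = make_single_fiber_network()
        fc = self._fresh_fc(net)
        rng = np.random.default_rng(7)
        cap = int(net.ligand_capacity[0])
        for _ in range(200):
            sample_bond_formation(fc, net, 0.01, rng, motor)
            fc.L_b = 0.03 + rng.uniform(0, 0.05)
            sample_bond_rupture(fc, net, 0.01, rng, motor)
            assert fc.n_b == net.ligand_bound[0]
            assert 0 <= fc.n_b <= cap
        release_fc(fc, net)
        assert net.ligand_bound[0] == 0

    def test_saturated_pool_blocks_binding(self, motor):
        net = make_single_fiber_network()
        fc = self._fresh_fc(net)
        net.ligand_bound[0] = net.ligand_capacity[0]
        rng = np.random.default_rng(1)
        assert sample_bond_formation(fc, net, 1.0, rng, motor) == 0

    def test_mean_bond_lifetime_matches_rate(self, motor):
        # survival of 10^4 unstressed bonds: mean lifetime = 1/k_off within 3 SE
        net = make_single_fiber_network(ligand_capacity=10**6)
        fc = self._fresh_fc(net)
        fc.n_b = 10**4
        net.ligand_bound[0] = fc.n_b
        n0 = fc.n_b
        rng = np.random.default_rng(3)
        dt, t, alive_integral = 0.01, 0.0, 0.0
        while fc.n_b > 0 and t < 30.0:
            alive_integral += fc.n_b * dt
            sample_bond_rupture(fc, net, dt, rng, motor)
            t += dt
        mean_lifetime = alive_integral / n0
        se = (1 / motor.k_off0) / math.sqrt(n0)
        assert abs(mean_lifetime - 1 / motor.k_off0) < 3 * se + dt


class TestAnchorGeometry:
    def test_perpendicular_tip_above_midpoint(self, motor):
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([1.0, 0.0, 0.0])
        tip = np.array([0.5, 0.05, 0.0])
        s, x_L, h_p, L_b, n_w, n_R = anchor_geometry(tip, a, b)
        assert s == pytest.approx(0.5)
        assert h_p == pytest.approx(0.05)
        assert L_b == pytest.approx(0.05)
        assert np.allclose(x_L, [0.5, 0, 0])
        assert np.allclose(n_w, [0, 1, 0])
        assert np.allclose(n_R, [0, -1, 0])

    def test_gate_rejects_beyond_100_nm(self, motor):
        net = make_single_fiber_network(center=(0.0, 0.0, 0.0), axis=(1, 0, 0))
        assert candidate_anchor(np.array([0.0, 0.15, 0.0]), net, motor) is None
        fc = candidate_anchor(np.array([0.0, 0.05, 0.0]), net, motor)
        assert fc is not None
        assert fc.h_p == pytest.approx(0.05)

    def test_equidistant_tie_breaks_to_lowest_ids(self, motor):
        pos = np.array([
            [0.0, 0.05, 0.0], [1.0, 0.05, 0.0],
            [0.0, -0.05, 0.0], [1.0, -0.05, 0.0],
        ])
        segs = np.array([[0, 1], [2, 3]], dtype=np.int32)
        net = network_from_arrays(pos, segs,
                                  [np.array([0, 1]), np.array([2, 3])],
                                  np.zeros((0, 3), dtype=np.int32), 300,
                                  (1.0, 1.0, 1.0))
        net.seg_chain[:] = [0, 1]
        fc = candidate_anchor(np.array([0.5, 0.0, 0.0]), net, motor)
        assert fc.seg_id == 0


class TestFCForce:
    def test_zero_bonds_zero_force(self, motor):
        fc = FocalComplex(seg_id=0, chain_id=0, s=0.3, ligand_node=0,
                          n_b=0, L_b=0.08, n_R=np.array([0, 0, 1.0]))
        F_tip, F_a, F_b = fc_force(fc, motor)
        assert np.all(F_tip == 0)

    def test_rest_length_bond_zero_force(self, motor):
        fc = FocalComplex(seg_id=0, chain_id=0, s=0.3, ligand_node=0,
                          n_b=50, L_b=motor.lambda_um, n_R=np.array([0, 0, 1.0]))
        F_tip, _, _ = fc_force(fc, motor)
        assert np.allclose(F_tip, 0)

    def test_hundred_bonds_ten_nm_stretch_is_one_nN(self, motor):
        fc = FocalComplex(seg_id=0, chain_id=0, s=0.25, ligand_node=0,
                          n_b=100, L_b=motor.lambda_um + 0.01,
                          n_R=np.array([1.0, 0, 0]))
        F_tip, F_a, F_b = fc_force(fc, motor)
        assert np.linalg.norm(F_tip) == pytest.approx(1000.0, rel=1e-12)

    def test_action_reaction_exact(self, motor):
        fc = FocalComplex(seg_id=0, chain_id=0, s=0.37, ligand_node=0,
                          n_b=123, L_b=0.071,
                          n_R=np.array([0.6, 0.8, 0.0]))
        F_tip, F_a, F_b = fc_force(fc, motor)
        assert np.all(F_tip + F_a + F_b == 0)


class TestAMCompartments:
    def test_stalled_motors_leave_rest_lengths(self, motor):
        filo = make_filopodium(np.zeros(3), [1, 0, 0], motor, length=3.0)
        rest = filo.am_rest.copy()
        am_update_and_forces(filo, motor.f_stall_pn, 1.0, motor)
        assert np.allclose(filo.am_rest, rest)

    def test_unloaded_contraction_rate(self, motor):
        # dL/dt = −2 v_m: 1 s at v_m0 = 10 nm/s shortens each rest by 20 nm
        filo = make_filopodium(np.zeros(3), [1, 0, 0], motor, length=3.0)
        rest = filo.am_rest.copy()
        am_update_and_forces(filo, 0.0, 1.0, motor)
        assert np.allclose(rest - filo.am_rest, 0.020, atol=1e-12)

    def test_unstressed_compartments_have_zero_force(self, motor):
        filo = make_filopodium(np.zeros(3), [1, 0, 0], motor, length=3.0)
        assert np.abs(am_forces(filo, motor)).max() < 1e-9

    def test_am_forces_sum_to_zero(self, motor):
        filo = make_filopodium(np.zeros(3), [1, 0, 0], motor, length=3.0)
        filo.am_rest *= 0.9
        F = am_forces(filo, motor)
        assert np.abs(F.sum(axis=0)).max() < 1e-9


class TestProtrusion:
    def test_along_vegf_gradient_with_stated_magnitude(self, motor):
        F = protrusion_force(np.array([1e-9, 0, 0]), FiloState.OUTGROWING,
                             np.array([0, 1.0, 0]), motor)
        assert np.allclose(F, [2000.0, 0, 0])

    def test_uniform_field_falls_back_to_growth_axis(self, motor):
        F = protrusion_force(np.zeros(3), FiloState.OUTGROWING,
                             np.array([0, 1.0, 0]), motor)
        assert np.allclose(F, [0, 2000.0, 0])

    def test_gated_off_outside_outgrowing(self, motor):
        F = protrusion_force(np.array([1e-9, 0, 0]), FiloState.RETRACTILE,
                             np.array([1.0, 0, 0]), motor)
        assert np.all(F == 0)


class TestStateMachine:
    def _filo(self, motor, length, state):
        filo = make_filopodium(np.zeros(3), [1, 0, 0], motor, length=length)
        filo.state = state
        return filo

    def test_outgrowing_to_tugging_on_fc_formation(self, motor):
        filo = self._filo(motor, 3.0, FiloState.OUTGROWING)
        filo.fc = FocalComplex(seg_id=0, chain_id=0, s=0.5, ligand_node=0, n_b=10)
        assert advance_state(filo, 0.1, motor) == FiloState.TUGGING

    def test_outgrowing_caps_at_max_length(self, motor):
        filo = self._filo(motor, motor.l_max_um + 0.01, FiloState.OUTGROWING)
        assert advance_state(filo, 0.1, motor) == FiloState.RETRACTILE

    def test_outgrowing_times_out_to_retractile(self, motor):
        filo = self._filo(motor, 3.0, FiloState.OUTGROWING)
        filo.t_in_state = motor.outgrow_budget_s + 1
        assert advance_state(filo, 0.1, motor) == FiloState.RETRACTILE

    def test_rupture_test_failure_returns_to_outgrowing(self, motor):
        filo = self._filo(motor, 3.0, FiloState.TUGGING)
        filo.fc = FocalComplex(seg_id=0, chain_id=0, s=0.5, ligand_node=0, n_b=0)
        assert advance_state(filo, 0.1, motor) == FiloState.OUTGROWING

    def test_tension_threshold_enters_contractile(self, motor):
        filo = self._filo(motor, 3.0, FiloState.TUGGING)
        filo.fc = FocalComplex(seg_id=0, chain_id=0, s=0.5, ligand_node=0, n_b=200)
        filo.tension = motor.contractile_threshold_pn + 1
        assert advance_state(filo, 0.1, motor) == FiloState.CONTRACTILE

    def test_retractile_decays_at_min_length(self, motor):
        filo = self._filo(motor, motor.l_min_um, FiloState.RETRACTILE)
        assert advance_state(filo, 0.1, motor) == FiloState.DECAY

    def test_timer_resets_on_transition_and_advances_otherwise(self, motor):
        filo = self._filo(motor, 3.0, FiloState.OUTGROWING)
        advance_state(filo, 0.5, motor)
        assert filo.t_in_state == 0.5
        filo.fc = FocalComplex(seg_id=0, chain_id=0, s=0.5, ligand_node=0, n_b=5)
        advance_state(filo, 0.5, motor)
        assert filo.state == FiloState.TUGGING
        assert filo.t_in_state == 0.0


class TestMeanSpeed:
    def test_stationary_is_zero(self):
        t = np.arange(11.0)
        p = np.tile([1.0, 2.0, 3.0], (11, 1))
        assert mean_speed(t, p, 0, 10) == 0.0

    def test_two_samples(self):
        # 5 μm apart over 100 s -> 0.05 μm/s
        t = np.array([0.0, 100.0])
        p = np.array([[0, 0, 0], [3.0, 4.0, 0.0]])
        assert mean_speed(t, p, 0, 100) == pytest.approx(0.05, rel=1e-12)

    @pytest.mark.parametrize("n_samples", [2, 5, 50])
    def test_uniform_motion_recovered_at_any_sampling(self, n_samples):
        v = 0.037
        t = np.linspace(0, 80, n_samples)
        p = np.outer(t * v, np.array([1.0, 0, 0]))
        assert mean_speed(t, p, 0, 80) == pytest.approx(v, rel=1e-12)

    def test_bad_window_rejected(self):
        t = np.array([0.0, 1.0])
        p = np.zeros((2, 3))
        with pytest.raises(ValueError):
            mean_speed(t, p, 1.0, 1.0)
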