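"""Fiber elasticity, force-energy consistency and the stretch test."""

import math

import numpy as np
import pytest

from filosim.io import make_random_chain_network, make_single_segment_network
from filosim.mechanics import (
    FiberMaterial,
    InsufficientDataError,
    StressStrainCurve,
    elastic_energy,
    elastic_forces,
    fit_bulk_modulus,
    run_stretch_test,
)


def material_with_stretch_modulus(kappa_pn: float) -> FiberMaterial:
    """Material whose κ_s equals the requested value exactly (r = 20 nm)."""
    r = 0.02
    return FiberMaterial(youngs_modulus=kappa_pn / (math.pi * r * r), radius_um=r)


def fd_gradient(network, mat, pos, h=1e-5):
    F = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for d in range(3):
            pp = pos.copy()
            pp[i, d] += h
            ep = elastic_energy(network, mat, pp)
            pp[i, d] -= 2 * h
            em = elastic_energy(network, mat, pp)
            F[i, d] = -(ep - em) / (2 * h)
    return F


class TestEnergy:
    def test_rest_configuration_has_zero_energy_and_forces(self, lattice, material):
        assert elastic_energy(lattice, material) < 1e-10
        assert np.abs(elastic_forces(lattice, material)).max() < 1e-8

    def test_single_segment_stretching_energy(self):
        # κ_s = 1.32 nN, L0 = 1 μm stretched to 1.2 μm -> 26.4 pN·μm
        net = make_single_segment_network(L0=1.0)
        mat = material_with_stretch_modulus(1320.0)
        pos = net.positions.copy()
        pos[1, 0] = 1.2
        assert elastic_energy(net, mat, pos) == pytest.approx(26.4, rel=1e-12)

    def test_single_segment_restoring_force(self):
        # strain 0.2 at κ_s = 1.32 nN -> end force 264 pN toward rest length
        net = make_single_segment_network(L0=1.0)
        mat = material_with_stretch_modulus(1320.0)
        pos = net.positions.copy()
        pos[1, 0] = 1.2
        F = elastic_forces(net, mat, pos)
        assert np.linalg.norm(F[1]) == pytest.approx(264.0, rel=1e-12)
        assert F[1, 0] < 0  # restoring

    def test_collinear_rest_chain_has_no_bending_force(self):
        net = make_random_chain_network(n_chains=1, n_nodes=4, seed=3)
        net.positions[:] = np.array(
            [[0, 0, 0], [0.5, 0, 0], [1.0, 0, 0], [1.5, 0, 0]])
        net.seg_L0[:] = 0.5
        net.tri_th0[:] = 0.0
        mat = FiberMaterial.from_diameter(34.0)
        assert elastic_energy(net, mat) < 1e-14
        assert np.abs(elastic_forces(net, mat)).max() < 1e-10

    def test_translation_and_rotation_invariance(self, material):
        net = make_random_chain_network(seed=5)
        rng = np.random.default_rng(0)
        pos = net.positions + rng.normal(0, 0.05, net.positions.shape)
        e0 = elastic_energy(net, material, pos)
        shifted = pos + np.array([1.7, -2.3, 0.9])
        assert elastic_energy(net, material, shifted) == pytest.approx(e0, rel=1e-12)
        th = 0.83
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0],
                      [0, 0, 1]])
        assert elastic_energy(net, material, pos @ R.T) == pytest.approx(e0, rel=1e-9)
        F = elastic_forces(net, material, pos)
        assert np.abs(F.sum(axis=0)).max() < 1e-9 * np.abs(F).max()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_forces_match_energy_gradient(self, material, seed):
        net = make_random_chain_network(n_chains=2, n_nodes=5, seed=seed)
        rng = np.random.default_rng(seed)
        pos = net.positions + rng.normal(0, 0.05, net.positions.shape)
        F = elastic_forces(net, material, pos)
        Ffd = fd_gradient(net, material, pos)
        denom = max(np.abs(Ffd).max(), 1.0)
        assert np.abs(F - Ffd).max() / denom < 1e-6

    def test_near_collinear_guard_matches_gradient(self, material):
        # bend within 1e-6 rad of straight: the guarded derivative must agree
        # with finite differences instead of blowing up
        net = make_random_chain_network(n_chains=1, n_nodes=3, seed=1)
        net.positions[:] = [[0, 0, 0], [1, 0, 0], [2, 1e-6, 0]]
        net.seg_L0[:] = np.linalg.norm(
            np.diff(net.positions, axis=0), axis=1)
        net.tri_th0[:] = 0.0
        F = elastic_forces(net, material)
        Ffd = fd_gradient(net, material, net.positions.copy())
        assert np.isfinite(F).all()
        assert np.abs(F - Ffd).max() < 1e-6 * max(np.abs(Ffd).max(), 1.0)


class TestStretchTest:
    def test_zero_strain_zero_stress(self, lattice, material):
        curve = run_stretch_test(lattice, material, max_strain=0.1,
                                 strain_step=0.05)
        assert curve.strains[0] == 0.0
        assert curve.stresses[0] == 0.0
        assert np.all(np.diff(curve.strains) > 0)

    def test_stress_increases_under_stretch(self, lattice, material):
        curve = run_stretch_test(lattice, material, max_strain=0.3,
                                 strain_step=0.1)
        assert curve.stresses[-1] > 0


class TestModulusFit:
    def test_linear_curve_recovery(self):
        eps = np.linspace(0, 0.75, 16)
        curve = StressStrainCurve(strains=eps, stresses=5000.0 * eps,
                                  stretch_speed_nm_s=0.5)
        assert fit_bulk_modulus(curve) == pytest.approx(5000.0, rel=1e-12)

    def test_fit_ignores_samples_outside_window(self):
        eps = np.linspace(0, 0.75, 16)
        stress = 5000.0 * eps
        # corrupt samples strictly outside [0.2, 0.7]
        stress[eps < 0.19] += 1e4
        stress[eps > 0.71] -= 1e4
        curve = StressStrainCurve(strains=eps, stresses=stress,
                                  stretch_speed_nm_s=0.5)
        assert fit_bulk_modulus(curve) == pytest.approx(5000.0, rel=1e-12)

    def test_noisy_curve_recovers_slope_within_regression_error(self):
        rng = np.random.default_rng(11)
        eps = np.linspace(0, 0.75, 31)
        sigma = 50.0
        stress = 4000.0 * eps + rng.normal(0, sigma, eps.size)
        curve = StressStrainCurve(strains=eps, stresses=stress,
                                  stretch_speed_nm_s=0.5)
        win = (eps >= 0.2) & (eps <= 0.7)
        x = eps[win]
        se = sigma / math.sqrt(((x - x.mean()) ** 2).sum())
        assert abs(fit_bulk_modulus(curve) - 4000.0) < 4 * se

    def test_insufficient_samples_in_window(self):
        curve = StressStrainCurve(strains=np.array([0.0, 0.5, 0.75]),
                                  stresses=np.array([0.0, 1.0, 2.0]),
                                  stretch_speed_nm_s=0.5)
        with pytest.raises(InsufficientDataError):
            fit_bulk_modulus(curve)


class TestMaterial:
    def test_derived_moduli_consistency(self):
        mat = FiberMaterial.from_diameter(34.0, 1.0e6)
        assert mat.area_um2 == pytest.approx(math.pi * 0.017**2, rel=1e-12)
        assert mat.stretch_modulus_pn == pytest.approx(1e6 * mat.area_um2, rel=1e-12)
        assert mat.bend_modulus_pn_um2 == pytest.approx(
            1e6 * math.pi * 0.017**4 / 4, rel=1e-12)

    def test_bend_modulus_override(self):
        mat = FiberMaterial.from_diameter(34.0, 1.0e6,
                                          bend_modulus_override=5e-3)
        assert mat.bend_modulus_pn_um2 == 5e-3
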