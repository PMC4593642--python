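"""Triple-membrane cell mechanics: couplings, FAs, SFs, lamellipodium."""

import numpy as np
import pytest

from filosim.cell import (
    StressFiber,
    build_cell,
    cortex_forces,
    coupled_membrane_cortex_rates,
    fa_forces,
    lamellipodium_forces,
    membrane_forces,
    nucleus_sf_forces,
    update_fas,
    update_sfs,
)
from filosim.config import CellConfig, MotorBindingConfig
from filosim.io import make_single_fiber_network


@pytest.fixture()
def cell_cfg():
    return CellConfig(n_membrane_nodes=162, radius_um=2.0)


@pytest.fixture()
def cell(cell_cfg):
    return build_cell(cell_cfg, center=(0.0, 0.0, 0.0))


class TestGeometry:
    def test_node_counts_and_volumes(self, cell, cell_cfg):
        assert cell.x_c.shape == cell.x_t.shape == cell.x_n.shape == (162, 3)
        assert cell.volume0_c > cell.volume0_n > 0

    def test_default_membrane_resolution(self):
        cfg = CellConfig()
        assert cfg.n_membrane_nodes == 549

    def test_normals_point_outward(self, cell):
        n = cell.outward_normals()
        radial = cell.x_c / np.linalg.norm(cell.x_c, axis=1, keepdims=True)
        assert np.all((n * radial).sum(axis=1) > 0.5)


class TestCoupledRates:
    def test_no_cortex_drag_decouples(self, cell_cfg):
        cell_cfg.c_cort_n_s_m = 0.0
        F_c = np.array([[1.0, 0, 0]])
        F_t = np.array([[0, 2.0, 0]])
        v_c, v_t = coupled_membrane_cortex_rates(F_c, F_t, cell_cfg)
        assert np.allclose(v_c, F_c / (cell_cfg.c_c_n_s_m * 1e6))
        assert np.allclose(v_t, F_t / (cell_cfg.c_t_n_s_m * 1e6))

    def test_symmetric_forces_give_equal_rates(self, cell_cfg):
        F = np.array([[1.0, -2.0, 3.0]])
        v_c, v_t = coupled_membrane_cortex_rates(F, F, cell_cfg)
        assert np.allclose(v_c, v_t)

    def test_matches_direct_linear_solve(self, cell_cfg):
        rng = np.random.default_rng(2)
        F_c = rng.normal(size=(25, 3))
        F_t = rng.normal(size=(25, 3))
        v_c, v_t = coupled_membrane_cortex_rates(F_c, F_t, cell_cfg)
        c_c = cell_cfg.c_c_n_s_m * 1e6
        c_t = cell_cfg.c_t_n_s_m * 1e6
        c_x = cell_cfg.c_cort_n_s_m * 1e6
        A = np.array([[c_c + c_x, -c_x], [-c_x, c_t + c_x]])
        for i in range(25):
            for d in range(3):
                vd = np.linalg.solve(A, [F_c[i, d], F_t[i, d]])
                assert v_c[i, d] == pytest.approx(vd[0], rel=1e-12)
                assert v_t[i, d] == pytest.approx(vd[1], rel=1e-12)


class TestForces:
    def test_resting_sphere_is_in_equilibrium(self, cell, cell_cfg):
        net = make_single_fiber_network(center=(100.0, 0, 0))  # out of reach
        out = membrane_forces(cell, net, cell_cfg, MotorBindingConfig())
        for key in ("elastic", "fa"):
            assert np.abs(out[key]).max() < 1e-8
        assert np.abs(out["cortex_c"]).max() < 1e-8

    def test_lamellipodium_force_is_exactly_300_pN_on_leading_edge(self, cell, cell_cfg):
        F = lamellipodium_forces(cell, cell_cfg)
        lead = cell.leading_edge(cell_cfg)
        mags = np.linalg.norm(F[lead], axis=1)
        assert np.allclose(mags, 300.0)
        others = np.setdiff1d(np.arange(cell.n_nodes), lead)
        assert np.abs(F[others]).max() == 0.0

    def test_cortex_pair_forces_cancel(self, cell, cell_cfg):
        cell.x_t *= 1.02  # disturb the cortex
        f_c, f_t = cortex_forces(cell, cell_cfg)
        assert np.all(f_c + f_t == 0)

    def test_fa_action_reaction(self, cell, cell_cfg):
        net = make_single_fiber_network(center=(2.05, 0.0, 0.0), axis=(0, 1, 0))
        motor = MotorBindingConfig()
        rng = np.random.default_rng(0)
        update_fas(cell, net, cell_cfg, motor, 1.0, rng)
        assert cell.fas, "a membrane node near the fiber should form an FA"
        F_c, ids, reac = fa_forces(cell, net, motor)
        total = F_c.sum(axis=0) + (reac.sum(axis=0) if len(reac) else 0)
        assert np.abs(total).max() < 1e-9

    def test_fa_bond_cap_respected(self, cell, cell_cfg):
        net = make_single_fiber_network(center=(2.05, 0.0, 0.0), axis=(0, 1, 0))
        motor = MotorBindingConfig()
        rng = np.random.default_rng(0)
        for _ in range(50):
            update_fas(cell, net, cell_cfg, motor, 0.5, rng)
        assert all(fa.n_b <= cell_cfg.fa_bond_cap for fa in cell.fas.values())
        assert any(fa.n_b > 0 for fa in cell.fas.values())

    def test_sf_action_reaction_and_rest_state(self, cell, cell_cfg):
        motor = MotorBindingConfig()
        rest = float(np.linalg.norm(cell.x_n[0] - cell.x_t[0]))
        cell.sfs[0] = StressFiber(t_node=0, n_node=0, rest=rest)
        F_t, F_n = nucleus_sf_forces(cell, cell_cfg, motor)
        # at rest length with stalled motors the SF exerts no force
        assert np.abs(F_t).max() < 1e-9
        cell.sfs[0].rest = 0.8 * rest
        F_t, F_n = nucleus_sf_forces(cell, cell_cfg, motor)
        # undeformed nucleus shell contributes no elastic force, so the SF
        # pair must cancel exactly between the two layers
        assert np.linalg.norm(F_t[0]) > 0
        assert np.allclose(F_t[0] + F_n[0], 0, atol=1e-9)

    def test_sf_contraction_shortens_rest_length(self, cell, cell_cfg):
        motor = MotorBindingConfig()
        rest = float(np.linalg.norm(cell.x_n[0] - cell.x_t[0]))
        cell.sfs[0] = StressFiber(t_node=0, n_node=0, rest=rest)
        update_sfs(cell, motor, 1.0)
        assert cell.sfs[0].rest == pytest.approx(rest - 0.020, abs=1e-9)

    def test_internal_forces_keep_center_of_mass(self, cell, cell_cfg):
        # elastic + cortex + SF with no external attachment: net force ~ 0
        motor = MotorBindingConfig()
        rng = np.random.default_rng(4)
        cell.x_c += rng.normal(0, 0.05, cell.x_c.shape)
        cell.x_n += rng.normal(0, 0.02, cell.x_n.shape)
        cell.sfs[3] = StressFiber(t_node=3, n_node=5, rest=0.5)
        net = make_single_fiber_network(center=(100.0, 0, 0))
        out = membrane_forces(cell, net, cell_cfg, motor)
        F_t, F_n = nucleus_sf_forces(cell, cell_cfg, motor)
        total = (out["elastic"].sum(axis=0) + out["cortex_c"].sum(axis=0)
                 + out["cortex_t"].sum(axis=0) + out["fa"].sum(axis=0)
                 + F_t.sum(axis=0) + F_n.sum(axis=0))
        scale = max(np.abs(out["elastic"]).max(), 1.0)
        assert np.abs(total).max() < 1e-8 * scale
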