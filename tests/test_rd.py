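"""Reaction–diffusion solver: conservation, closed forms, secretion."""

import math

import numpy as np
import pytest

from filosim.config import RDConfig
from filosim.io import make_single_fiber_network
from filosim.rd import (
    make_fields,
    rd_step,
    secretion_sources,
    update_ecm_integrity,
)


@pytest.fixture()
def cfg():
    return RDConfig()


class TestDiffusion:
    def test_mass_conserved_without_reactions(self, cfg):
        f = make_fields((10, 10, 10), cfg)
        f.data["mmp2"][:] = 0
        f.data["mmp2"][4, 5, 6] = 1e-6
        m0 = f.total_mass("mmp2")
        for _ in range(1000):
            rd_step(f, cfg, {}, 0.5, vegf_dirichlet=False, reactions=False)
        assert abs(f.total_mass("mmp2") - m0) / m0 < 1e-6

    def test_zero_fields_stay_zero(self, cfg):
        f = make_fields((8, 8, 8), cfg)
        for sp in f.data:
            f.data[sp][:] = 0
        for _ in range(10):
            rd_step(f, cfg, {}, 1.0, vegf_dirichlet=False)
        assert all(np.all(v == 0) for v in f.data.values())

    def test_dirichlet_face_holds_vegf(self, cfg):
        f = make_fields((10, 6, 6), cfg)
        rd_step(f, cfg, {}, 1.0)
        assert np.allclose(f.data["vegf"][-1], cfg.c_vegf_far_m)
        g = f.vegf_gradient_at(np.array([5.0, 3.0, 3.0]))
        assert g[0] > 0  # gradient points toward the far face


class TestReactions:
    def test_vegf_exponential_decay(self, cfg):
        # uniform field: C(t) = C0 exp(−8.2e-6 t) to 1e-4 relative at t = 1e5 s
        f = make_fields((4, 4, 4), cfg)
        c0 = 2e-9
        f.data["vegf"][:] = c0
        t, dt = 0.0, 10.0
        while t < 1e5 - 1e-9:
            rd_step(f, cfg, {}, dt, vegf_dirichlet=False, diffusion=False)
            t += dt
        expected = c0 * math.exp(-cfg.k_vegf_decay * 1e5)
        assert np.allclose(f.data["vegf"], expected, rtol=1e-4)

    def test_timp2_mmp2_association_removes_both_equally(self, cfg):
        cfg_iso = RDConfig(
            k_vegf_decay=0, k_mmp2_decay=0, k_ligand_decay=0, k_ecm_deg=0,
            k_on_timp2_mt1mmp=0, k_on_complex_mt1mmp=0, k_off_complex=0,
        )
        f = make_fields((6, 6, 6), cfg_iso)
        f.data["timp2"][:] = 3e-7
        f.data["mmp2"][:] = 1e-7
        m_t0, m_m0 = f.total_mass("timp2"), f.total_mass("mmp2")
        for _ in range(500):
            rd_step(f, cfg_iso, {}, 0.01, vegf_dirichlet=False, diffusion=False)
        d_t = m_t0 - f.total_mass("timp2")
        d_m = m_m0 - f.total_mass("mmp2")
        assert d_m > 0
        assert d_t == pytest.approx(d_m, rel=1e-3)

    def test_all_species_remain_nonnegative(self, cfg):
        f = make_fields((8, 6, 6), cfg)
        src = secretion_sources([np.array([1.5, 2.5, 2.5])], f)
        for _ in range(200):
            rd_step(f, cfg, src, 0.5)
        for sp, arr in f.data.items():
            assert np.all(arr >= 0), sp

    def test_ligand_production_bounded_by_ecm_loss(self, cfg):
        f = make_fields((4, 4, 4), cfg)
        f.data["mmp2"][:] = 1e-5      # aggressive proteolysis
        lig0 = f.total_mass("ligand")
        ecm0 = f.total_mass("ecm")
        cfg_nd = RDConfig(k_ligand_decay=0.0)
        for _ in range(100):
            rd_step(f, cfg_nd, {}, 0.5, vegf_dirichlet=False, diffusion=False)
        gained = f.total_mass("ligand") - lig0
        lost = ecm0 - f.total_mass("ecm")
        assert gained == pytest.approx(lost, rel=1e-6)


class TestSecretion:
    def test_no_filopodia_empty_map(self, cfg):
        f = make_fields((8, 8, 8), cfg)
        assert secretion_sources([], f) == {}

    def test_single_root_single_cell(self, cfg):
        f = make_fields((8, 8, 8), cfg)
        src = secretion_sources([np.array([3.2, 4.7, 0.1])], f)
        assert src == {(3, 4, 0): 1}

    def test_two_roots_in_one_cell_add(self, cfg):
        f = make_fields((8, 8, 8), cfg)
        src = secretion_sources(
            [np.array([3.2, 4.7, 0.1]), np.array([3.9, 4.2, 0.5])], f)
        assert src == {(3, 4, 0): 2}

    def test_out_of_grid_root_clamps(self, cfg):
        f = make_fields((8, 8, 8), cfg)
        src = secretion_sources([np.array([-5.0, 100.0, 4.0])], f)
        assert src == {(0, 7, 4): 1}

    def test_sources_feed_mt1mmp_and_timp2(self, cfg):
        f = make_fields((8, 6, 6), cfg)
        src = secretion_sources([np.array([2.5, 2.5, 2.5])], f)
        rd_step(f, cfg, src, 1.0)
        assert f.data["mt1mmp"][2, 2, 2] > 0
        assert f.data["timp2"].max() > 0


class TestECMIntegrity:
    def test_no_protease_no_change(self, cfg):
        f = make_fields((6, 6, 6), cfg)
        net = make_single_fiber_network(center=(3.0, 3.0, 3.0))
        c0 = net.ecm_conc.copy()
        integ = update_ecm_integrity(f, net, cfg, 10.0)
        assert np.array_equal(net.ecm_conc, c0)
        assert np.all(integ == 1.0)

    def test_constant_mmp2_gives_exponential_decay(self, cfg):
        # C_MMP2 = 1 μM -> effective rate 1.04 s⁻¹
        f = make_fields((6, 6, 6), cfg)
        f.data["mmp2"][:] = 1e-6
        net = make_single_fiber_network(center=(3.0, 3.0, 3.0))
        for _ in range(10):
            update_ecm_integrity(f, net, cfg, 0.1)
        assert np.allclose(net.ecm_conc / net.ecm_conc0,
                           math.exp(-1.04), rtol=1e-9)

    def test_integrity_monotone_nonincreasing(self, cfg):
        f = make_fields((6, 6, 6), cfg)
        net = make_single_fiber_network(center=(3.0, 3.0, 3.0))
        rng = np.random.default_rng(0)
        prev = net.integrity()
        for _ in range(20):
            f.data["mmp2"][:] = rng.uniform(0, 2e-6)
            cur = update_ecm_integrity(f, net, cfg, 0.5)
            assert np.all(cur <= prev + 1e-15)
            prev = cur
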