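"""Engine orchestration: equilibrium, convergence, contacts, determinism."""

import numpy as np
import pytest

from filosim.config import SimConfig
from filosim.engine import (
    compute_forces,
    make_state,
    nucleate_filopodium,
    refresh_active_domain,
    refresh_contacts,
    resolve_contacts,
    run_replicate,
    run_simulation,
    step,
)
from filosim.io import make_single_fiber_network


def mechanics_only_state(network, seed=1, **cfg_kw):
    cfg = SimConfig(seed=seed)
    for k, v in cfg_kw.items():
        setattr(cfg.engine, k, v)
    return make_state(cfg, network.copy(), cell=None, seed=seed,
                      with_fields=False, freeze_boundary=False)


class TestEquilibriumAndConvergence:
    def test_rest_network_stays_put(self, lattice):
        state = mechanics_only_state(lattice, event_dt=0.5)
        p0 = state.pos.copy()
        for _ in range(20):          # 10 s of simulated time
            step(state)
        assert np.abs(state.pos - p0).max() < 1e-9

    def test_convergence_against_stiff_ode_oracle(self, material):
        # overdamped relaxation of a kicked chain network, checked against an
        # independent adaptive stiff integration of dx/dt = F/C
        from scipy.integrate import solve_ivp

        from filosim.io import make_random_chain_network
        from filosim.mechanics import elastic_forces

        net = make_random_chain_network(n_chains=2, n_nodes=5, seed=2)
        rng = np.random.default_rng(0)
        kick = rng.normal(0, 0.05, net.positions.shape)

        def rhs(t, y):
            F = elastic_forces(net, material, y.reshape(-1, 3))
            return (F / 1000.0).ravel()

        ref = solve_ivp(rhs, (0, 2.0), (net.positions + kick).ravel(),
                        method="LSODA", rtol=1e-10, atol=1e-12).y[:, -1]

        def final_positions(tol):
            state = mechanics_only_state(net, ode_tolerance=tol)
            state.pos[:net.n_nodes] += kick
            while state.time < 2.0 - 1e-9:
                step(state)
            return state.pos[:net.n_nodes].ravel()

        coarse_err = np.abs(final_positions(1e-4) - ref).max()
        fine_err = np.abs(final_positions(5e-5) - ref).max()
        assert coarse_err < 1e-4           # within the coarser tolerance
        assert fine_err <= coarse_err + 1e-9
        assert np.abs(final_positions(1e-4)
                      - final_positions(5e-5)).max() < 1e-4

    def test_internal_forces_sum_to_zero(self, lattice):
        state = mechanics_only_state(lattice)
        rng = np.random.default_rng(3)
        state.pos[:lattice.n_nodes] += rng.normal(0, 0.05,
                                                  (lattice.n_nodes, 3))
        F = compute_forces(state, include_external=False)
        scale = max(np.abs(F).max(), 1.0)
        assert np.abs(F.sum(axis=0)).max() < 1e-9 * scale


class TestContacts:
    def test_no_penetration_no_correction(self):
        net = make_single_fiber_network(center=(5.0, 0, 0))
        state = mechanics_only_state(net)
        filo = nucleate_filopodium(state, 0, (1.0, 0, 0))
        # park the filopodium far from the fiber
        state.pos[filo.rows] -= np.array([20.0, 0, 0])
        F = resolve_contacts(state)
        assert np.abs(F).max() == 0.0

    def test_penetrating_node_is_repelled_with_reaction(self, motor):
        net = make_single_fiber_network(center=(3.0, 0.0, 0.0), axis=(0, 1, 0))
        state = mechanics_only_state(net)
        filo = nucleate_filopodium(state, 0, (1.0, 0, 0))
        tip = filo.tip_index()
        r_f = state.material.radius_um
        state.pos[tip] = np.array([3.0 + 0.5 * r_f, 0.05, 0.0])
        F = resolve_contacts(state)
        assert F[tip, 0] > 0                       # pushed off the fiber axis
        reaction = F[:net.n_nodes].sum(axis=0)
        assert np.allclose(F[tip] + reaction, 0, atol=1e-9)

    def test_relaxation_reduces_penetration(self):
        net = make_single_fiber_network(center=(3.0, 0.0, 0.0), axis=(0, 1, 0))
        state = mechanics_only_state(net, event_dt=0.01)
        state.frozen[:net.n_nodes] = True
        state.immobile[:net.n_nodes] = True
        filo = nucleate_filopodium(state, 0, (1.0, 0, 0))
        tip = filo.tip_index()
        r_f = state.material.radius_um
        state.pos[tip] = np.array([3.0 + 0.5 * r_f, 0.0, 0.0])
        refresh_contacts(state)
        depth0 = r_f - abs(state.pos[tip, 0] - 3.0)
        step(state)
        depth1 = r_f - abs(state.pos[tip, 0] - 3.0)
        assert depth1 < depth0


@pytest.fixture(scope="module")
def small_cfg():
    cfg = SimConfig(seed=5, preset="pore1.5", replicates=2)
    cfg.network.domain_um = (9.0, 5.0, 5.0)
    cfg.cell.radius_um = 1.5
    cfg.cell.n_membrane_nodes = 162
    cfg.engine.ode_tolerance = 1e-3
    cfg.engine.dt_max = 0.15
    cfg.engine.event_dt = 0.3
    return cfg


class TestRuns:
    def test_zero_total_time_gives_empty_trajectory(self, small_cfg):
        out = run_simulation(small_cfg, total_time=0.0)
        assert out["replicates"] == []

    def test_replicates_and_summary(self, small_cfg):
        out = run_simulation(small_cfg, total_time=30.0)
        ok = [r for r in out["replicates"] if not r.get("failed")]
        assert len(ok) == 2
        assert np.isfinite(out["summary"]["mean_tip"])
        assert len(out["seeds"]) == 2

    def test_bitwise_determinism(self, small_cfg):
        a = run_replicate(small_cfg, 123, total_time=20.0)
        b = run_replicate(small_cfg, 123, total_time=20.0)
        assert a["mean_tip"] == b["mean_tip"]
        assert a["centroid_advance_x"] == b["centroid_advance_x"]
        assert a["log"] == b["log"]


class TestActiveDomain:
    def test_far_nodes_freeze(self, lattice):
        state = mechanics_only_state(lattice)
        state.config.engine.active_domain_radius_um = 1.0
        filo = nucleate_filopodium(state, 0, (1.0, 0, 0))
        refresh_active_domain(state)
        p = state.net_pos
        centers = [state.pos[filo.tip_index()]]
        d = np.linalg.norm(p - centers[0], axis=1)
        far = d > 1.0
        assert state.immobile[:lattice.n_nodes][far].all()
        assert not state.immobile[:lattice.n_nodes][~far].all()
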