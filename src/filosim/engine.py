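"""Coupled simulation engine: force assembly, adaptive overdamped
integration, stochastic events, contacts, reaction–diffusion coupling and
full invasion runs.

Time structure.  The mechanical degrees of freedom (network, triple-membrane
cell, filopodia) are advanced between *event macro-steps* (default 0.05 s)
by an adaptive embedded Euler/Heun pair honoring [dt_min, dt_max] with local
error ≤ ``ode_tolerance``; bond formation/rupture, anchor re-projection,
acto-myosin rest-length updates and the filopodium state machine fire once
per macro-step with the elapsed dt.  Reaction–diffusion and ECM degradation
advance at a coarser cadence (default 0.5 s; the biochemical time scales are
slow relative to mechanics), and neighbor structures / the active domain
refresh on their own timers.

Geometry.  All mechanical nodes live in one flat position array:
[network | membrane | transduce | nucleus | ghost anchors | filopodium
slots].  Ghost nodes are frozen helpers (tether anchors, virtual roots for
the single-filopodium harness).  Contact repulsion treats membrane and
filopodial nodes against fiber cylinders with an effective node radius added
to the fiber radius, discovered through a uniform spatial hash over segment
midpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import _kernels
from .cell import (
    CellBody,
    build_cell,
    update_fas,
    update_polarization,
    update_sfs,
    volume_penalty_forces,
)
from .config import EngineConfig, SimConfig
from .filopodium import (
    FiloState,
    FocalComplex,
    advance_state,
    am_stiffness,
    candidate_anchor,
    fc_force,
    mean_speed,
    myosin_velocity,
    release_fc,
    reproject_anchor,
    sample_bond_formation,
    sample_bond_rupture,
)
from .mechanics import FiberMaterial
from .network import FiberNetwork, NetworkParams, apply_crosslink_degradation, build_network
from .rd import make_fields, rd_step, secretion_sources, update_ecm_integrity

_GRID_REBUILD_S = 2.0   # spatial-hash staleness; margins account for drift

_EMPTY_I = np.zeros(0, dtype=np.int32)
_EMPTY_F = np.zeros(0, dtype=np.float64)
_EMPTY_F3 = np.zeros((0, 3), dtype=np.float64)


@dataclass
class EngineFilo:
    """Engine-side filopodium: rows into the global position array."""

    slot: int
    root_node: int                  # global index of the root (membrane/ghost)
    rows: np.ndarray                # (n_am,) global indices of shaft nodes
    am_rest: np.ndarray             # (n_am,)
    growth_axis: np.ndarray
    state: FiloState = FiloState.OUTGROWING
    t_in_state: float = 0.0
    fc: FocalComplex | None = None
    tension: float = 0.0
    born: float = 0.0
    _pos: np.ndarray | None = None  # reference to the global array

    @property
    def n_am(self) -> int:
        return self.rows.shape[0]

    def chain_indices(self) -> np.ndarray:
        return np.concatenate(([self.root_node], self.rows))

    def node_positions(self) -> np.ndarray:
        return self._pos[self.chain_indices()]

    def tip_index(self) -> int:
        return int(self.rows[-1])

    def length(self) -> float:
        p = self.node_positions()
        return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())

    def spans(self) -> np.ndarray:
        p = self.node_positions()
        return np.linalg.norm(np.diff(p, axis=0), axis=1)


@dataclass
class SimulationState:
    config: SimConfig
    network: FiberNetwork
    material: FiberMaterial
    cell: CellBody | None
    fields: object | None
    pos: np.ndarray
    drag: np.ndarray
    immobile: np.ndarray
    frozen: np.ndarray
    off_net: int
    off_c: int
    off_t: int
    off_n: int
    off_ghost: int
    off_filo: int
    n_ghost: int
    rng_binding: np.random.Generator
    rng_rupture: np.random.Generator
    rng_nucleation: np.random.Generator
    filopodia: list[EngineFilo] = field(default_factory=list)
    time: float = 0.0
    seg_klin: np.ndarray | None = None
    tri_kb: np.ndarray | None = None
    static_springs: tuple | None = None
    extra_springs: tuple | None = None   # e.g. harness tethers
    pair_a: np.ndarray = field(default_factory=lambda: _EMPTY_I.copy())
    pair_b: np.ndarray = field(default_factory=lambda: _EMPTY_I.copy())
    pair_drags: tuple[float, float, float] = (1000.0, 1000.0, 0.0)
    net_stiff: np.ndarray | None = None
    tri_act_cache: np.ndarray | None = None
    dt_next: float = 1e-3
    grid: tuple | None = None
    contact_pairs: tuple | None = None
    free_slots: list[int] = field(default_factory=list)
    last_grid_build: float = -1e9
    last_neighbor: float = -1e9
    last_rd: float = 0.0
    last_active: float = -1e9
    last_centroid: np.ndarray | None = None
    degradation_enabled: bool = True
    diagnostics: dict = field(default_factory=dict)

    # ---- convenience views -------------------------------------------------

    @property
    def net_pos(self) -> np.ndarray:
        return self.pos[: self.off_c]

    def cell_views(self) -> None:
        """Point the CellBody arrays into the global position array."""
        if self.cell is None:
            return
        n = self.cell.n_nodes
        self.cell.x_c = self.pos[self.off_c: self.off_c + n]
        self.cell.x_t = self.pos[self.off_t: self.off_t + n]
        self.cell.x_n = self.pos[self.off_n: self.off_n + n]


# ---------------------------------------------------------------------------
# state construction


def make_state(config: SimConfig, network: FiberNetwork,
               cell: CellBody | None, seed: int,
               n_ghost: int = 0, with_fields: bool = True,
               freeze_boundary: bool = True) -> SimulationState:
    eng = config.engine
    mcfg = config.motor
    n_net = network.n_nodes
    n_c = cell.n_nodes if cell is not None else 0
    max_filo = mcfg.max_filopodia
    n_filo_rows = max_filo * mcfg.n_am

    off_c = n_net
    off_t = off_c + n_c
    off_n = off_t + n_c
    off_ghost = off_n + n_c
    off_filo = off_ghost + n_ghost
    n_tot = off_filo + n_filo_rows

    pos = np.zeros((n_tot, 3))
    pos[:n_net] = network.positions
    network.positions = pos[:n_net]          # view into the global array
    if cell is not None:
        pos[off_c: off_c + n_c] = cell.x_c
        pos[off_t: off_t + n_c] = cell.x_t
        pos[off_n: off_n + n_c] = cell.x_n

    # drag / mobility
    drag = np.full(n_tot, config.material.drag_n_s_per_m * 1e6)
    c_c = config.cell.c_c_n_s_m * 1e6
    c_t = config.cell.c_t_n_s_m * 1e6
    c_x = config.cell.c_cort_n_s_m * 1e6
    drag[off_c: off_c + n_c] = c_c
    drag[off_t: off_t + n_c] = c_t
    drag[off_n: off_n + n_c] = config.cell.c_n_n_s_m * 1e6
    drag[off_filo:] = mcfg.drag_n_s_per_m * 1e6
    pair_a = np.arange(off_c, off_c + n_c, dtype=np.int32)
    pair_b = np.arange(off_t, off_t + n_c, dtype=np.int32)

    # frozen: domain boundary shell of the network + ghosts + parked filo rows
    frozen = np.zeros(n_tot, dtype=bool)
    if freeze_boundary:
        margin = eng.boundary_freeze_um
        p = network.positions
        near = np.zeros(n_net, dtype=bool)
        for ax in range(3):
            near |= (p[:, ax] < p[:, ax].min() + margin) | \
                    (p[:, ax] > p[:, ax].max() - margin)
        frozen[:n_net] = near
    frozen[off_ghost: off_filo] = True
    frozen[off_filo:] = True                  # slots unfreeze on nucleation

    seq = np.random.SeedSequence(seed)
    sub = seq.spawn(3)
    state = SimulationState(
        config=config,
        network=network,
        material=FiberMaterial.from_config(config.material),
        cell=cell,
        fields=None,
        pos=pos,
        drag=drag,
        immobile=frozen.copy(),
        frozen=frozen,
        off_net=0, off_c=off_c, off_t=off_t, off_n=off_n,
        off_ghost=off_ghost, off_filo=off_filo, n_ghost=n_ghost,
        rng_binding=np.random.Generator(np.random.PCG64(sub[0])),
        rng_rupture=np.random.Generator(np.random.PCG64(sub[1])),
        rng_nucleation=np.random.Generator(np.random.PCG64(sub[2])),
        pair_a=pair_a, pair_b=pair_b, pair_drags=(c_c, c_t, c_x),
        free_slots=list(range(max_filo)),
        degradation_enabled=config.rd.degradation_enabled,
    )
    state.cell_views()
    state.seg_klin = state.material.stretch_modulus_pn / network.seg_L0
    state.tri_kb = (state.material.bend_modulus_pn_um2 / network.tri_L0
                    if len(network.tri_L0) else _EMPTY_F.copy())
    state.static_springs = _static_cell_springs(state)
    if with_fields:
        state.fields = make_fields(network.domain_um, config.rd,
                                   ecm_conc0_m=network.ecm_conc0)
    state.last_centroid = cell.centroid().copy() if cell is not None else None
    return state


def _static_cell_springs(state: SimulationState):
    cfg = state.config.cell
    cell = state.cell
    if cell is None:
        return (_EMPTY_I.copy(), _EMPTY_I.copy(), _EMPTY_F.copy(), _EMPTY_F.copy())
    k_memb = cfg.kappa_memb_n_m * 1e6
    k_cort = cfg.kappa_cort_n_m * 1e6
    e = cell.edges
    parts_a, parts_b, parts_k, parts_l = [], [], [], []
    for off, rest in ((state.off_c, cell.edge_rest_c),
                      (state.off_t, cell.edge_rest_t),
                      (state.off_n, cell.edge_rest_n)):
        parts_a.append(e[:, 0] + off)
        parts_b.append(e[:, 1] + off)
        parts_k.append(np.full(len(e), k_memb))
        parts_l.append(rest)
    n = cell.n_nodes
    parts_a.append(np.arange(state.off_c, state.off_c + n))
    parts_b.append(np.arange(state.off_t, state.off_t + n))
    parts_k.append(np.full(n, k_cort))
    parts_l.append(cell.cortex_rest)
    return (np.concatenate(parts_a).astype(np.int32),
            np.concatenate(parts_b).astype(np.int32),
            np.concatenate(parts_k),
            np.concatenate(parts_l))


# ---------------------------------------------------------------------------
# neighbor structures


@njit(cache=True)
def _grid_pairs(qpos, qids, qrad, ptr, items, origin, ncell, csize,
                mid, seg_a, seg_b, pos, half_seg, margin, cap):
    out_n = np.empty(cap, dtype=np.int32)
    out_s = np.empty(cap, dtype=np.int32)
    out_d = np.empty(cap)
    count = 0
    nx, ny, nz = ncell[0], ncell[1], ncell[2]
    for q in range(qpos.shape[0]):
        x = qpos[q, 0]
        y = qpos[q, 1]
        z = qpos[q, 2]
        r_direct = qrad[q]
        r_mid = r_direct + half_seg + margin
        ci = int((x - origin[0]) / csize)
        cj = int((y - origin[1]) / csize)
        ck = int((z - origin[2]) / csize)
        for di in range(-1, 2):
            ii = ci + di
            if ii < 0 or ii >= nx:
                continue
            for dj in range(-1, 2):
                jj = cj + dj
                if jj < 0 or jj >= ny:
                    continue
                for dk in range(-1, 2):
                    kk = ck + dk
                    if kk < 0 or kk >= nz:
                        continue
                    c = (ii * ny + jj) * nz + kk
                    for m in range(ptr[c], ptr[c + 1]):
                        sidx = items[m]
                        dx = mid[sidx, 0] - x
                        dy = mid[sidx, 1] - y
                        dz = mid[sidx, 2] - z
                        if dx * dx + dy * dy + dz * dz > r_mid * r_mid:
                            continue
                        ia = seg_a[sidx]
                        ib = seg_b[sidx]
                        ex = pos[ib, 0] - pos[ia, 0]
                        ey = pos[ib, 1] - pos[ia, 1]
                        ez = pos[ib, 2] - pos[ia, 2]
                        ee = ex * ex + ey * ey + ez * ez
                        px = x - pos[ia, 0]
                        py = y - pos[ia, 1]
                        pz = z - pos[ia, 2]
                        if ee < 1e-18:
                            t = 0.0
                        else:
                            t = (px * ex + py * ey + pz * ez) / ee
                            if t < 0.0:
                                t = 0.0
                            elif t > 1.0:
                                t = 1.0
                        ddx = px - t * ex
                        ddy = py - t * ey
                        ddz = pz - t * ez
                        dist2 = ddx * ddx + ddy * ddy + ddz * ddz
                        lim = r_direct + margin
                        if dist2 < lim * lim and count < cap:
                            out_n[count] = qids[q]
                            out_s[count] = sidx
                            out_d[count] = np.sqrt(dist2)
                            count += 1
    return out_n[:count], out_s[:count], out_d[:count]


def _build_segment_grid(state: SimulationState, csize: float = 0.6):
    net = state.network
    act = np.where(net.seg_active)[0].astype(np.int32)
    mid = 0.5 * (net.positions[net.segments[act, 0]]
                 + net.positions[net.segments[act, 1]])
    lo = state.pos.min(axis=0) - 1.0
    hi = state.pos.max(axis=0) + 1.0
    ncell = np.maximum(((hi - lo) / csize).astype(np.int64), 1)
    idx = np.floor((mid - lo) / csize).astype(np.int64)
    idx = np.clip(idx, 0, ncell - 1)
    flat = (idx[:, 0] * ncell[1] + idx[:, 1]) * ncell[2] + idx[:, 2]
    order = np.argsort(flat, kind="stable")
    counts = np.bincount(flat, minlength=int(ncell.prod()))
    ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    half_seg = float(net.seg_L0[act].max() / 2.0) if act.size else 0.0
    mid_all = 0.5 * (net.positions[net.segments[:, 0]]
                     + net.positions[net.segments[:, 1]])
    state.grid = (ptr, act[order].astype(np.int32), lo, ncell.astype(np.int64),
                  csize, half_seg, np.ascontiguousarray(mid_all))
    state.last_grid_build = state.time


def query_segments(state: SimulationState, qpos: np.ndarray, qids: np.ndarray,
                   qrad: np.ndarray, margin: float = 0.1):
    """(node, segment, distance) triples within per-node radius + margin."""
    if state.grid is None:
        _build_segment_grid(state)
    ptr, items, lo, ncell, csize, half_seg, mid = state.grid
    net = state.network
    cap = max(64, qpos.shape[0] * 256)
    return _grid_pairs(
        np.ascontiguousarray(qpos), qids.astype(np.int32),
        np.ascontiguousarray(qrad), ptr, items, lo, ncell, csize,
        mid, net.segments[:, 0], net.segments[:, 1],
        state.pos, half_seg, margin, cap,
    )


def _contact_query_nodes(state: SimulationState):
    eng = state.config.engine
    ids, rad = [], []
    if state.cell is not None:
        n = state.cell.n_nodes
        ids.append(np.arange(state.off_c, state.off_c + n))
        rad.append(np.full(n, eng.membrane_node_radius_um))
    for filo in state.filopodia:
        ids.append(filo.rows)
        rad.append(np.full(filo.n_am, eng.filopodium_node_radius_um))
    if not ids:
        return np.zeros(0, dtype=int), np.zeros(0)
    return np.concatenate(ids), np.concatenate(rad)


def refresh_contacts(state: SimulationState) -> None:
    eng = state.config.engine
    ids, rad = _contact_query_nodes(state)
    if ids.size == 0:
        state.contact_pairs = (_EMPTY_I.copy(), _EMPTY_I.copy(), _EMPTY_I.copy(),
                               _EMPTY_F.copy(), _EMPTY_F.copy())
        return
    rad_eff = rad + state.material.radius_um
    node, seg, _ = query_segments(state, state.pos[ids], ids, rad_eff,
                                  margin=0.15)
    na = state.network.segments[seg, 0]
    nb = state.network.segments[seg, 1]
    # per-pair contact range: node radius + fiber radius
    is_filo = node >= state.off_filo
    rng_pair = np.where(is_filo,
                        eng.filopodium_node_radius_um,
                        eng.membrane_node_radius_um) + state.material.radius_um
    k = np.full(node.shape[0], eng.contact_stiffness_pn_um)
    state.contact_pairs = (node.astype(np.int32), na.astype(np.int32),
                           nb.astype(np.int32), rng_pair, k)


# ---------------------------------------------------------------------------
# per-batch assembly


def _dynamic_springs(state: SimulationState):
    mcfg = state.config.motor
    a, b, k, L0 = [], [], [], []
    for filo in state.filopodia:
        idx = filo.chain_indices()
        kap = am_stiffness(filo.am_rest, mcfg)
        a.append(idx[:-1])
        b.append(idx[1:])
        k.append(kap)
        L0.append(filo.am_rest)
    if state.cell is not None:
        for sf in state.cell.sfs.values():
            a.append([state.off_t + sf.t_node])
            b.append([state.off_n + sf.n_node])
            k.append([float(am_stiffness(sf.rest, mcfg))])
            L0.append([sf.rest])
    if not a:
        return (_EMPTY_I.copy(), _EMPTY_I.copy(), _EMPTY_F.copy(), _EMPTY_F.copy())
    return (np.concatenate(a).astype(np.int32), np.concatenate(b).astype(np.int32),
            np.concatenate([np.atleast_1d(x) for x in k]).astype(float),
            np.concatenate([np.atleast_1d(x) for x in L0]).astype(float))


def _bond_point_springs(state: SimulationState):
    mcfg = state.config.motor
    node, na, nb, s, k, rest = [], [], [], [], [], []
    segs = state.network.segments
    for filo in state.filopodia:
        fc = filo.fc
        if fc is not None and fc.n_b > 0:
            node.append(filo.tip_index())
            na.append(segs[fc.seg_id, 0])
            nb.append(segs[fc.seg_id, 1])
            s.append(fc.s)
            k.append(fc.n_b * mcfg.kappa_lr_pn_um)
            rest.append(mcfg.lambda_um)
    if state.cell is not None:
        for fa in state.cell.fas.values():
            if fa.n_b == 0:
                continue
            node.append(state.off_c + fa.node)
            na.append(segs[fa.seg_id, 0])
            nb.append(segs[fa.seg_id, 1])
            s.append(fa.s)
            k.append(fa.n_b * mcfg.kappa_lr_pn_um)
            rest.append(mcfg.lambda_um)
    if not node:
        return (_EMPTY_I.copy(), _EMPTY_I.copy(), _EMPTY_I.copy(),
                _EMPTY_F.copy(), _EMPTY_F.copy(), _EMPTY_F.copy())
    return (np.asarray(node, dtype=np.int32), np.asarray(na, dtype=np.int32),
            np.asarray(nb, dtype=np.int32), np.asarray(s, dtype=float),
            np.asarray(k, dtype=float), np.asarray(rest, dtype=float))


def _external_forces(state: SimulationState, include_external: bool = True):
    nodes, forces = [], []
    if include_external:
        mcfg = state.config.motor
        for filo in state.filopodia:
            if filo.state == FiloState.OUTGROWING:
                tip = state.pos[filo.tip_index()]
                if state.fields is not None:
                    g = state.fields.vegf_gradient_at(tip)
                else:
                    g = np.zeros(3)
                norm = np.linalg.norm(g)
                direction = g / norm if norm > 1e-30 else filo.growth_axis
                nodes.append([filo.tip_index()])
                forces.append(mcfg.f_p_max_pn * direction[None, :])
        if state.cell is not None:
            ccfg = state.config.cell
            lead = state.cell.leading_edge(ccfg)
            if lead.size:
                n = state.cell.outward_normals()
                nodes.append(state.off_c + lead)
                forces.append(ccfg.lamellipodium_force_pn * n[lead])
    # volume-preservation penalties (internal to each shell, net zero force)
    if state.cell is not None:
        ccfg = state.config.cell
        cell = state.cell
        fc_vol = volume_penalty_forces(cell.x_c, cell.triangles, cell.volume0_c,
                                       ccfg.volume_penalty_pn_um5)
        fn_vol = volume_penalty_forces(cell.x_n, cell.triangles, cell.volume0_n,
                                       ccfg.volume_penalty_pn_um5)
        nodes.append(np.arange(state.off_c, state.off_c + cell.n_nodes))
        forces.append(fc_vol)
        nodes.append(np.arange(state.off_n, state.off_n + cell.n_nodes))
        forces.append(fn_vol)
    if not nodes:
        return _EMPTY_I.copy(), _EMPTY_F3.copy()
    return (np.concatenate(nodes).astype(np.int32),
            np.ascontiguousarray(np.concatenate(forces, axis=0)))


def _kernel_args(state: SimulationState, include_external: bool = True):
    net = state.network
    sa, sb, sk, sl = state.static_springs
    da, db, dk, dl = _dynamic_springs(state)
    if state.extra_springs is not None:
        ea, eb, ek, el = state.extra_springs
        sa = np.concatenate([sa, ea]).astype(np.int32)
        sb = np.concatenate([sb, eb]).astype(np.int32)
        sk = np.concatenate([sk, ek])
        sl = np.concatenate([sl, el])
    spr_a = np.concatenate([sa, da]).astype(np.int32)
    spr_b = np.concatenate([sb, db]).astype(np.int32)
    spr_k = np.concatenate([sk, dk])
    spr_l = np.concatenate([sl, dl])
    psp = _bond_point_springs(state)
    ext_n, ext_f = _external_forces(state, include_external)
    if state.contact_pairs is None:
        refresh_contacts(state)
    con = state.contact_pairs
    if state.tri_act_cache is None:
        state.tri_act_cache = net.tri_active()
    tri_act = state.tri_act_cache
    return (net.segments[:, 0], net.segments[:, 1], state.seg_klin,
            net.seg_L0, net.seg_active,
            net.triples[:, 0], net.triples[:, 1], net.triples[:, 2],
            state.tri_kb, net.tri_th0, tri_act,
            spr_a, spr_b, spr_k, spr_l,
            psp[0], psp[1], psp[2], psp[3], psp[4], psp[5],
            ext_n, ext_f,
            con[0], con[1], con[2], con[3], con[4])


def _node_stiffness(state: SimulationState, args) -> np.ndarray:
    """Per-node summed interaction stiffness (pN/μm) for the linearly
    implicit mobility.  The network-segment part is cached and refreshed
    only when degradation changes the coupling set."""
    n = state.pos.shape[0]
    if state.net_stiff is None:
        net = state.network
        act = net.seg_active
        idx = np.concatenate([net.segments[act, 0], net.segments[act, 1]])
        w = np.concatenate([state.seg_klin[act], state.seg_klin[act]])
        state.net_stiff = np.bincount(idx, weights=w, minlength=n)
    stiff = state.net_stiff.copy()
    (_, _, _, _, _, _, _, _, _, _, _,
     spr_a, spr_b, spr_k, _,
     psp_node, psp_na, psp_nb, psp_s, psp_k, _,
     _, _,
     con_node, con_na, con_nb, _, con_k) = args
    idx = np.concatenate([spr_a, spr_b, psp_node, psp_na, psp_nb,
                          con_node, con_na, con_nb])
    w = np.concatenate([spr_k, spr_k, psp_k, psp_k * (1 - psp_s), psp_k * psp_s,
                        con_k, con_k, con_k])
    if idx.size:
        stiff += np.bincount(idx, weights=w, minlength=n)
    return stiff


def compute_forces(state: SimulationState, include_external: bool = True) -> np.ndarray:
    """Assembled force on every node (pN) at the current positions."""
    args = _kernel_args(state, include_external)
    F = np.zeros_like(state.pos)
    _kernels.assemble_forces(state.pos, F, *args)
    return F


def resolve_contacts(state: SimulationState) -> np.ndarray:
    """Contact (elastic repulsive) corrections only, as a per-node force
    array; symmetric reactions on fiber nodes included."""
    refresh_contacts(state)
    con = state.contact_pairs
    args = (_EMPTY_I, _EMPTY_I, _EMPTY_F, _EMPTY_F, np.zeros(0, dtype=bool),
            _EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_F, _EMPTY_F, np.zeros(0, dtype=bool),
            _EMPTY_I, _EMPTY_I, _EMPTY_F, _EMPTY_F,
            _EMPTY_I, _EMPTY_I, _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F,
            _EMPTY_I, _EMPTY_F3,
            con[0], con[1], con[2], con[3], con[4])
    F = np.zeros_like(state.pos)
    _kernels.assemble_forces(state.pos, F, *args)
    return F


# ---------------------------------------------------------------------------
# events


def _update_filopodia_events(state: SimulationState, dt: float) -> None:
    mcfg = state.config.motor
    net = state.network
    for filo in list(state.filopodia):
        tip = state.pos[filo.tip_index()]
        # FC geometry + kinetics
        if filo.fc is not None:
            if not net.seg_active[filo.fc.seg_id]:
                release_fc(filo.fc, net)
                filo.fc = None
            else:
                reproject_anchor(filo.fc, tip, net)
                if filo.fc.L_b > mcfg.fc_detach_distance_um:
                    release_fc(filo.fc, net)
                    filo.fc = None
        if filo.fc is not None:
            sample_bond_rupture(filo.fc, net, dt, state.rng_rupture, mcfg)
            sample_bond_formation(filo.fc, net, dt, state.rng_binding, mcfg)
        elif filo.state in (FiloState.OUTGROWING, FiloState.TUGGING,
                            FiloState.CONTRACTILE):
            node, seg, dist = query_segments(
                state, tip[None, :], np.array([filo.tip_index()]),
                np.array([mcfg.contact_range_um]), margin=0.0)
            if seg.size:
                fc = candidate_anchor(tip, net, mcfg, seg_ids=seg)
                if fc is not None:
                    filo.fc = fc
                    sample_bond_formation(fc, net, dt, state.rng_binding, mcfg)
        # tension and AM rest-length dynamics
        if filo.fc is not None and filo.fc.n_b > 0:
            F_tip, _, _ = fc_force(filo.fc, mcfg)
            filo.tension = float(np.linalg.norm(F_tip))
        else:
            filo.tension = 0.0
        if filo.state == FiloState.OUTGROWING:
            # plastic growth: rest lengths trail the spans so the shaft stays
            # taut while the tip advances at the polymerization rate
            growth = mcfg.v_poly_um_s * dt / filo.n_am
            filo.am_rest = np.minimum(filo.am_rest + growth,
                                      filo.spans() + 0.01)
            np.clip(filo.am_rest, mcfg.am_rest_floor_um, None, out=filo.am_rest)
        elif filo.state in (FiloState.TUGGING, FiloState.CONTRACTILE,
                            FiloState.RETRACTILE):
            load = 0.0 if filo.state == FiloState.RETRACTILE else min(
                filo.tension, mcfg.f_stall_pn)
            v_m = myosin_velocity(load, mcfg)
            filo.am_rest -= 2.0 * v_m * dt
            np.clip(filo.am_rest, mcfg.am_rest_floor_um, None, out=filo.am_rest)
        # state machine
        prev = filo.state
        advance_state(filo, dt, mcfg)
        if filo.state != prev:
            if filo.state == FiloState.RETRACTILE and filo.fc is not None:
                release_fc(filo.fc, net)
                filo.fc = None
            if filo.state == FiloState.INACTIVE:
                _remove_filopodium(state, filo)


def _remove_filopodium(state: SimulationState, filo: EngineFilo) -> None:
    if filo.fc is not None:
        release_fc(filo.fc, state.network)
        filo.fc = None
    state.frozen[filo.rows] = True
    state.immobile[filo.rows] = True
    state.free_slots.append(filo.slot)
    state.filopodia.remove(filo)


def nucleate_filopodium(state: SimulationState, root_node: int,
                        axis: np.ndarray, length: float | None = None) -> EngineFilo:
    mcfg = state.config.motor
    if not state.free_slots:
        raise RuntimeError("no free filopodium slots")
    slot = state.free_slots.pop(0)
    rows = np.arange(state.off_filo + slot * mcfg.n_am,
                     state.off_filo + (slot + 1) * mcfg.n_am)
    L = mcfg.l_min_um if length is None else length
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    root = state.pos[root_node]
    ts = np.linspace(L / mcfg.n_am, L, mcfg.n_am)
    state.pos[rows] = root[None, :] + ts[:, None] * axis[None, :]
    state.frozen[rows] = False
    state.immobile[rows] = False
    filo = EngineFilo(
        slot=slot, root_node=root_node, rows=rows,
        am_rest=np.full(mcfg.n_am, L / mcfg.n_am),
        growth_axis=axis, state=FiloState.OUTGROWING, born=state.time,
        _pos=state.pos,
    )
    state.filopodia.append(filo)
    return filo


def _maybe_nucleate(state: SimulationState, dt: float) -> None:
    mcfg = state.config.motor
    if state.cell is None or not state.free_slots:
        return
    if state.rng_nucleation.random() >= mcfg.nucleation_rate_per_s * dt:
        return
    cell = state.cell
    normals = cell.outward_normals()
    p = cell.polarization / np.linalg.norm(cell.polarization)
    cosang = normals @ p
    occupied = {f.root_node - state.off_c for f in state.filopodia}
    eligible = [i for i in range(cell.n_nodes)
                if cosang[i] >= math.cos(math.radians(mcfg.polarity_angle_deg))
                and i not in occupied]
    if not eligible:
        return
    node = int(state.rng_nucleation.choice(np.asarray(eligible)))
    nucleate_filopodium(state, state.off_c + node, normals[node])


def _rd_events(state: SimulationState, dt: float) -> None:
    if state.fields is None:
        return
    roots = [state.pos[f.root_node] for f in state.filopodia]
    sources = secretion_sources(roots, state.fields)
    rd_step(state.fields, state.config.rd, sources, dt)
    if state.degradation_enabled:
        update_ecm_integrity(state.fields, state.network, state.config.rd, dt)
        before = int(state.network.seg_active.sum())
        apply_crosslink_degradation(state.network, state.rng_rupture)
        if int(state.network.seg_active.sum()) != before:
            state.net_stiff = None
            state.tri_act_cache = None


def refresh_active_domain(state: SimulationState) -> None:
    """Freeze network nodes outside the active radius around the cell and
    filopodial tips (they act as fixed boundaries)."""
    eng = state.config.engine
    n_net = state.off_c
    active = np.zeros(n_net, dtype=bool)
    centers = []
    if state.cell is not None:
        centers.append(state.cell.centroid())
    for f in state.filopodia:
        centers.append(state.pos[f.tip_index()])
    if not centers:
        active[:] = True
    else:
        p = state.net_pos
        for c in centers:
            d2 = ((p - c[None, :]) ** 2).sum(axis=1)
            active |= d2 <= eng.active_domain_radius_um**2
    state.immobile[:n_net] = state.frozen[:n_net] | ~active
    state.last_active = state.time


# ---------------------------------------------------------------------------
# stepping


def step(state: SimulationState, config: EngineConfig | None = None) -> SimulationState:
    """One event macro-step: integrate mechanics over ``event_dt`` with the
    adaptive embedded pair, then apply stochastic events, then (on cadence)
    reaction–diffusion, degradation and housekeeping."""
    eng = config if config is not None else state.config.engine
    if state.time - state.last_grid_build >= _GRID_REBUILD_S:
        _build_segment_grid(state)
    if state.time - state.last_active >= eng.active_domain_refresh_s:
        refresh_active_domain(state)
    if state.time - state.last_neighbor >= eng.neighbor_refresh_s:
        refresh_contacts(state)
        state.last_neighbor = state.time

    dt_ev = eng.event_dt
    args = _kernel_args(state)
    stiff = _node_stiffness(state, args)
    c_c, c_t, c_x = state.pair_drags
    dt_next, n_acc, n_rej, n_forced = _kernels.integrate_batch(
        state.pos, dt_ev, state.dt_next, eng.ode_tolerance,
        eng.dt_min, eng.dt_max,
        state.drag, state.immobile, stiff, state.pair_a, state.pair_b,
        c_c, c_t, c_x, *args)
    state.dt_next = dt_next
    d = state.diagnostics
    d["accepted"] = d.get("accepted", 0) + n_acc
    d["rejected"] = d.get("rejected", 0) + n_rej
    d["forced"] = d.get("forced", 0) + n_forced

    _update_filopodia_events(state, dt_ev)
    _maybe_nucleate(state, dt_ev)

    state.time += dt_ev
    if state.time - state.last_rd >= eng.rd_interval:
        elapsed = state.time - state.last_rd
        _rd_events(state, elapsed)
        if state.cell is not None:
            update_fas_with_candidates(state, elapsed)
            update_sfs(state.cell, state.config.motor, elapsed)
            c = state.cell.centroid()
            update_polarization(state.cell, c - state.last_centroid,
                                state.config.cell)
            state.last_centroid = c.copy()
        state.last_rd = state.time
    return state


def update_fas_with_candidates(state: SimulationState, dt: float) -> None:
    """FA maintenance with spatially pre-selected candidate segments."""
    cell = state.cell
    cfg = state.config.cell
    n = cell.n_nodes
    ids = np.arange(state.off_c, state.off_c + n)
    rad = np.full(n, cfg.fa_range_um)
    node, seg, dist = query_segments(state, state.pos[ids], ids, rad, margin=0.0)
    cand: dict[int, list[int]] = {}
    for nd, sg in zip(node - state.off_c, seg):
        cand.setdefault(int(nd), []).append(int(sg))
    cand_arr = {k: np.asarray(v, dtype=int) for k, v in cand.items()}
    update_fas(cell, state.network, cfg, state.config.motor, dt,
               state.rng_binding, candidate_segs=cand_arr)


# ---------------------------------------------------------------------------
# full runs


def _build_invasion_state(config: SimConfig, seed: int) -> SimulationState:
    streams = np.random.SeedSequence(seed).spawn(2)
    net_seed = int(np.random.Generator(np.random.PCG64(streams[0])).integers(2**31 - 1))
    params = NetworkParams.from_config(config.network,
                                       config.material.fiber_diameter_nm,
                                       net_seed)
    network = build_network(params)
    ccfg = config.cell
    center = np.array([ccfg.radius_um + 0.2,
                       network.domain_um[1] / 2.0,
                       network.domain_um[2] / 2.0])
    cell = build_cell(ccfg, center)
    state = make_state(config, network, cell, seed)
    # seed a few leading-edge filopodia so invasion starts promptly
    normals = cell.outward_normals()
    cosang = normals @ cell.polarization
    order = np.argsort(-cosang)
    n_init = min(3, config.motor.max_filopodia)
    for i in order[:n_init]:
        nucleate_filopodium(state, state.off_c + int(i), normals[int(i)])
    _build_segment_grid(state)
    refresh_active_domain(state)
    refresh_contacts(state)
    return state


def run_replicate(config: SimConfig, seed: int,
                  total_time: float | None = None) -> dict:
    """One invasion replicate; returns trajectories and speed statistics."""
    state = _build_invasion_state(config, seed)
    eng = state.config.engine
    total = eng.total_time_s if total_time is None else total_time
    cadence = eng.snapshot_cadence_s
    next_snap = 0.0
    tracks: dict[tuple[int, float], dict] = {}
    centroid0 = state.cell.centroid().copy()
    log_rows = []
    centroid_t, centroid_x = [], []
    while state.time < total - 1e-9:
        if state.time >= next_snap - 1e-9:
            _record(state, tracks, log_rows)
            centroid_t.append(state.time)
            centroid_x.append(float(state.cell.centroid()[0]))
            next_snap += cadence
        step(state)
    _record(state, tracks, log_rows)
    centroid_t.append(state.time)
    centroid_x.append(float(state.cell.centroid()[0]))

    tip_speeds, root_speeds = [], []
    for key, tr in tracks.items():
        t = np.asarray(tr["t"])
        if t.size < 2 or t[-1] - t[0] < 10 * cadence:
            continue
        tip_speeds.append(mean_speed(t, np.asarray(tr["tip"]), t[0], t[-1]))
        root_speeds.append(mean_speed(t, np.asarray(tr["root"]), t[0], t[-1]))
    centroid_adv = float(state.cell.centroid()[0] - centroid0[0])
    return {
        "seed": seed,
        "tip_speeds": tip_speeds,
        "root_speeds": root_speeds,
        "mean_tip": float(np.mean(tip_speeds)) if tip_speeds else 0.0,
        "mean_root": float(np.mean(root_speeds)) if root_speeds else 0.0,
        "centroid_advance_x": centroid_adv,
        "centroid_t": centroid_t,
        "centroid_x": centroid_x,
        "log": log_rows,
        "diagnostics": dict(state.diagnostics),
    }


def _record(state: SimulationState, tracks: dict, log_rows: list) -> None:
    for filo in state.filopodia:
        key = (filo.slot, filo.born)
        tr = tracks.setdefault(key, {"t": [], "tip": [], "root": []})
        tr["t"].append(state.time)
        tip = state.pos[filo.tip_index()].copy()
        tr["tip"].append(tip)
        tr["root"].append(state.pos[filo.root_node].copy())
        log_rows.append((state.time, filo.slot, int(filo.state), filo.length(),
                         filo.fc.n_b if filo.fc else 0, filo.tension,
                         tip[0], tip[1], tip[2]))


def run_simulation(config: SimConfig, total_time: float | None = None) -> dict:
    """N replicates with distinct derived seeds; aggregates Eq.-style
    time-averaged tip/root speeds as mean ± SEM."""
    streams = config.rng_streams()
    seeds = streams.replicate_seeds(config.replicates)
    if total_time is not None and total_time <= 0:
        return {"replicates": [], "summary": {}, "seeds": seeds}
    reps = []
    for s in seeds:
        try:
            reps.append(run_replicate(config, s, total_time))
        except Exception as exc:  # noqa: BLE001 — a failed replicate must not sink the study
            reps.append({"seed": s, "failed": True, "error": repr(exc)})
    ok = [r for r in reps if not r.get("failed")]
    tips = np.array([r["mean_tip"] for r in ok])
    roots = np.array([r["mean_root"] for r in ok])
    n = max(len(ok), 1)
    summary = {
        "n": len(ok),
        "mean_tip": float(tips.mean()) if len(ok) else float("nan"),
        "sem_tip": float(tips.std(ddof=1) / math.sqrt(n)) if len(ok) > 1 else 0.0,
        "mean_root": float(roots.mean()) if len(ok) else float("nan"),
        "sem_root": float(roots.std(ddof=1) / math.sqrt(n)) if len(ok) > 1 else 0.0,
    }
    return {"replicates": reps, "summary": summary, "seeds": seeds}


# ---------------------------------------------------------------------------
# single-filopodium regime harness


def run_single_filopodium(anchor_stiffness_pn_um: float | None,
                          total_time: float, seed: int,
                          config: SimConfig | None = None,
                          log_every: float = 0.5) -> dict:
    """One filopodium against a single tethered fiber.

    ``anchor_stiffness_pn_um`` tethers each fiber node to its initial
    position (None → fiber pinned rigidly).  The filopodium re-nucleates
    from a fixed virtual root after decay, so load-and-fail cycling can
    repeat.  Returns a time log of state, length, bond count and tension.
    """
    from .io import make_single_fiber_network  # local import to avoid cycle

    cfg = config if config is not None else SimConfig(seed=seed)
    cfg.seed = seed
    network = make_single_fiber_network(center=(3.0, 0.0, 0.0), axis=(0, 1, 0),
                                        length=3.0, n_seg=6)
    n_fiber = network.n_nodes
    state = make_state(cfg, network, cell=None, seed=seed,
                       n_ghost=1 + n_fiber, with_fields=False,
                       freeze_boundary=False)
    root_node = state.off_ghost
    state.pos[root_node] = np.array([0.0, 0.0, 0.0])
    ghost_fiber = np.arange(state.off_ghost + 1, state.off_ghost + 1 + n_fiber)
    state.pos[ghost_fiber] = network.positions

    if anchor_stiffness_pn_um is None:
        state.frozen[:n_fiber] = True
        state.immobile[:n_fiber] = True
    else:
        state.extra_springs = (
            np.arange(n_fiber, dtype=np.int32),
            ghost_fiber.astype(np.int32),
            np.full(n_fiber, float(anchor_stiffness_pn_um)),
            np.zeros(n_fiber),
        )

    nucleate_filopodium(state, root_node, axis=(1.0, 0.0, 0.0))
    _build_segment_grid(state)
    refresh_active_domain(state)
    refresh_contacts(state)

    rows = []
    next_log = 0.0
    respawn_at = None
    while state.time < total_time - 1e-9:
        step(state)
        if not state.filopodia:
            if respawn_at is None:
                respawn_at = state.time + 1.0
            elif state.time >= respawn_at:
                nucleate_filopodium(state, root_node, axis=(1.0, 0.0, 0.0))
                respawn_at = None
        if state.time >= next_log - 1e-9:
            if state.filopodia:
                f = state.filopodia[0]
                rows.append((state.time, int(f.state), f.length(),
                             f.fc.n_b if f.fc else 0, f.tension))
            else:
                rows.append((state.time, int(FiloState.INACTIVE), 0.0, 0, 0.0))
            next_log += log_every
    t, s, L, nb, ten = (np.array(x) for x in zip(*rows))
    return {"t": t, "state": s, "length": L, "bonds": nb, "tension": ten}


__all__ = [
    "SimulationState",
    "EngineFilo",
    "make_state",
    "step",
    "compute_forces",
    "resolve_contacts",
    "refresh_contacts",
    "refresh_active_domain",
    "nucleate_filopodium",
    "run_replicate",
    "run_simulation",
    "run_single_filopodium",
]
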