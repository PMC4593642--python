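"""Simplified triple-membrane cell mechanics.

Three concentric 549-node shells — cell membrane, force-transduce layer and
nuclear membrane — share one triangulation.  Membrane and nucleus carry edge
springs (κ_memb) plus a volume-preservation penalty; each membrane node is
tied to its transduce partner by a cortical Kelvin–Voigt element (spring
κ_cort here; the dashpot C_cort lives in the coupled 2×2 mobility of the
membrane/transduce rate equations).  Focal adhesions (FAs) are stochastic
Bell-kinetics bond clusters (cap 100 bonds/node, slower unstressed turnover
than filopodial FCs) anchoring membrane nodes to the nearest fiber point;
mature FAs nucleate contractile stress fibers (single acto-myosin
compartments) from the transduce layer to the nearest nucleus node.  A
constant 300 pN lamellipodium force pushes leading-edge nodes (within 60°
of the polarization axis) outward.

The detailed focal-adhesion maturation and stress-fiber remodelling models
this structure descends from are implemented here in deliberately minimal
form: the force balance and its action–reaction couplings are kept, the
remodelling biochemistry is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .config import CellConfig, MotorBindingConfig
from .filopodium import am_stiffness, bell_koff, binding_probability, myosin_velocity
from .network import FiberNetwork


@dataclass
class FocalAdhesion:
    """Bond cluster anchoring a membrane node to a fiber segment."""

    node: int                      # membrane node index (cell-local)
    seg_id: int
    s: float
    ligand_node: int
    n_b: int = 0


@dataclass
class StressFiber:
    """Single contractile AM compartment from a transduce node to a nucleus
    node; rest length shortens at 2·v_m under its own tension."""

    t_node: int
    n_node: int
    rest: float


@dataclass
class CellBody:
    x_c: np.ndarray                # (N, 3) membrane
    x_t: np.ndarray                # (N, 3) transduce layer
    x_n: np.ndarray                # (N, 3) nucleus
    edges: np.ndarray              # (E, 2) shared shell topology
    triangles: np.ndarray          # (T, 3) outward-oriented
    edge_rest_c: np.ndarray
    edge_rest_t: np.ndarray
    edge_rest_n: np.ndarray
    cortex_rest: np.ndarray        # (N,)
    volume0_c: float
    volume0_n: float
    polarization: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    fas: dict[int, FocalAdhesion] = field(default_factory=dict)
    sfs: dict[int, StressFiber] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.x_c.shape[0]

    def centroid(self) -> np.ndarray:
        return self.x_c.mean(axis=0)

    def outward_normals(self) -> np.ndarray:
        """Per-node unit normals (area-weighted average of facet normals)."""
        normals = np.zeros_like(self.x_c)
        a = self.x_c[self.triangles[:, 0]]
        b = self.x_c[self.triangles[:, 1]]
        c = self.x_c[self.triangles[:, 2]]
        fn = np.cross(b - a, c - a)
        for k in range(3):
            np.add.at(normals, self.triangles[:, k], fn)
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        return normals / np.where(norm < 1e-30, 1.0, norm)

    def leading_edge(self, cfg: CellConfig) -> np.ndarray:
        """Nodes whose outward normal lies within the leading-edge cone."""
        n = self.outward_normals()
        p = self.polarization / np.linalg.norm(self.polarization)
        cosang = n @ p
        return np.where(cosang >= math.cos(math.radians(cfg.leading_edge_angle_deg)))[0]


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly-uniform unit-sphere sampling."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + math.sqrt(5)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def build_cell(cfg: CellConfig, center) -> CellBody:
    center = np.asarray(center, dtype=float)
    unit = fibonacci_sphere(cfg.n_membrane_nodes)
    hull = ConvexHull(unit)
    tris = hull.simplices.copy()
    # orient facets outward
    a, b, c = unit[tris[:, 0]], unit[tris[:, 1]], unit[tris[:, 2]]
    fn = np.cross(b - a, c - a)
    centers = (a + b + c) / 3.0
    flip = (fn * centers).sum(axis=1) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    edges = set()
    for t in tris:
        s = np.sort(t)
        edges.update([(s[0], s[1]), (s[0], s[2]), (s[1], s[2])])
    edges = np.array(sorted(edges), dtype=np.int32)

    r = cfg.radius_um
    x_c = center + r * unit
    x_t = center + cfg.transduce_radius_frac * r * unit
    x_n = center + cfg.nucleus_radius_frac * r * unit

    def rest(x):
        return np.linalg.norm(x[edges[:, 1]] - x[edges[:, 0]], axis=1)

    cell = CellBody(
        x_c=x_c, x_t=x_t, x_n=x_n, edges=edges, triangles=tris,
        edge_rest_c=rest(x_c), edge_rest_t=rest(x_t), edge_rest_n=rest(x_n),
        cortex_rest=np.linalg.norm(x_c - x_t, axis=1),
        volume0_c=enclosed_volume(x_c, tris),
        volume0_n=enclosed_volume(x_n, tris),
    )
    return cell


def enclosed_volume(x: np.ndarray, tris: np.ndarray) -> float:
    a, b, c = x[tris[:, 0]], x[tris[:, 1]], x[tris[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def volume_gradient(x: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """∂V/∂x per node for the divergence-form enclosed volume."""
    g = np.zeros_like(x)
    a, b, c = x[tris[:, 0]], x[tris[:, 1]], x[tris[:, 2]]
    np.add.at(g, tris[:, 0], np.cross(b, c) / 6.0)
    np.add.at(g, tris[:, 1], np.cross(c, a) / 6.0)
    np.add.at(g, tris[:, 2], np.cross(a, b) / 6.0)
    return g


# ---------------------------------------------------------------------------
# force pieces (numpy reference implementations; the engine mirrors these
# through its compiled assembly and a test pins the two together)


def edge_spring_forces(x, edges, rest, k) -> np.ndarray:
    d = x[edges[:, 1]] - x[edges[:, 0]]
    L = np.linalg.norm(d, axis=1)
    L = np.where(L < 1e-12, 1e-12, L)
    f = (k * (L - rest) / L)[:, None] * d
    F = np.zeros_like(x)
    np.add.at(F, edges[:, 0], f)
    np.add.at(F, edges[:, 1], -f)
    return F


def volume_penalty_forces(x, tris, v0, k_v) -> np.ndarray:
    """F = k_V (V0 − V) ∇V: restores the enclosed volume."""
    v = enclosed_volume(x, tris)
    return k_v * (v0 - v) * volume_gradient(x, tris)


def cortex_forces(cell: CellBody, cfg: CellConfig):
    """Kelvin–Voigt spring part: equal/opposite pair forces on x_c and x_t."""
    k = cfg.kappa_cort_n_m * 1e6  # N/m → pN/μm
    d = cell.x_t - cell.x_c
    L = np.linalg.norm(d, axis=1)
    L = np.where(L < 1e-12, 1e-12, L)
    f = (k * (L - cell.cortex_rest) / L)[:, None] * d
    return f, -f  # on x_c, on x_t


def lamellipodium_forces(cell: CellBody, cfg: CellConfig) -> np.ndarray:
    """Constant-magnitude protrusive force on leading-edge nodes, along the
    outward membrane normal."""
    F = np.zeros_like(cell.x_c)
    lead = cell.leading_edge(cfg)
    n = cell.outward_normals()
    F[lead] = cfg.lamellipodium_force_pn * n[lead]
    return F


def fa_forces(cell: CellBody, network: FiberNetwork, motor: MotorBindingConfig):
    """FA bond-cluster forces on membrane nodes and their exact reactions on
    fiber nodes.  Returns (F_c, fiber_node_ids, fiber_forces)."""
    F = np.zeros_like(cell.x_c)
    ids: list[int] = []
    reac: list[np.ndarray] = []
    for fa in cell.fas.values():
        if fa.n_b == 0:
            continue
        na, nb = network.segments[fa.seg_id]
        anchor = (1 - fa.s) * network.positions[na] + fa.s * network.positions[nb]
        d = anchor - cell.x_c[fa.node]
        L = float(np.linalg.norm(d))
        if L < 1e-12:
            continue
        f = fa.n_b * motor.kappa_lr_pn_um * (L - motor.lambda_um) * d / L
        F[fa.node] += f
        ids.extend([int(na), int(nb)])
        reac.extend([-f * (1 - fa.s), -f * fa.s])
    return F, np.array(ids, dtype=int), np.array(reac).reshape(-1, 3)


def membrane_forces(cell: CellBody, network: FiberNetwork, cfg: CellConfig,
                    motor: MotorBindingConfig, dt: float | None = None,
                    rng: np.random.Generator | None = None):
    """All CC-row force terms at the membrane nodes.

    When ``dt`` and ``rng`` are given, FA stochastic kinetics are advanced
    first (same Monte-Carlo machinery as filopodial FCs).  Returns a dict of
    named per-node force arrays plus the fiber reaction (ids, forces).
    """
    if dt is not None and rng is not None:
        update_fas(cell, network, cfg, motor, dt, rng)
    k_memb = cfg.kappa_memb_n_m * 1e6
    F_e = edge_spring_forces(cell.x_c, cell.edges, cell.edge_rest_c, k_memb)
    F_e += volume_penalty_forces(cell.x_c, cell.triangles, cell.volume0_c,
                                 cfg.volume_penalty_pn_um5)
    F_cort_c, F_cort_t = cortex_forces(cell, cfg)
    F_lam = lamellipodium_forces(cell, cfg)
    F_fa, fiber_ids, fiber_F = fa_forces(cell, network, motor)
    return {
        "elastic": F_e,
        "cortex_c": F_cort_c,
        "cortex_t": F_cort_t,
        "lamellipodium": F_lam,
        "fa": F_fa,
        "fiber_ids": fiber_ids,
        "fiber_forces": fiber_F,
    }


def nucleus_sf_forces(cell: CellBody, cfg: CellConfig, motor: MotorBindingConfig):
    """CN-row forces: nuclear membrane elasticity plus stress-fiber pulls;
    SF action–reaction on the transduce layer is returned alongside."""
    k_memb = cfg.kappa_memb_n_m * 1e6
    F_n = edge_spring_forces(cell.x_n, cell.edges, cell.edge_rest_n, k_memb)
    F_n += volume_penalty_forces(cell.x_n, cell.triangles, cell.volume0_n,
                                 cfg.volume_penalty_pn_um5)
    F_t = np.zeros_like(cell.x_t)
    for sf in cell.sfs.values():
        d = cell.x_n[sf.n_node] - cell.x_t[sf.t_node]
        L = float(np.linalg.norm(d))
        if L < 1e-12:
            continue
        kappa = float(am_stiffness(sf.rest, motor))
        f = kappa * (L - sf.rest) * d / L
        F_t[sf.t_node] += f
        F_n[sf.n_node] -= f
    return F_t, F_n


def coupled_membrane_cortex_rates(F_c: np.ndarray, F_t: np.ndarray,
                                  cfg: CellConfig):
    """Solve the Kelvin–Voigt-coupled membrane/transduce rate pair.

    The per-node system
        (C_c + C_cort) ẋ_c − C_cort ẋ_t = F_c
        −C_cort ẋ_c + (C_t + C_cort) ẋ_t = F_t
    inverts to the shared 2×2 mobility with determinant
    C_c·C_t + C_cort·(C_c + C_t) > 0.
    """
    c_c = cfg.c_c_n_s_m * 1e6
    c_t = cfg.c_t_n_s_m * 1e6
    c_x = cfg.c_cort_n_s_m * 1e6
    det = c_c * c_t + c_x * (c_c + c_t)
    m11 = (c_t + c_x) / det
    m12 = c_x / det
    m22 = (c_c + c_x) / det
    return m11 * F_c + m12 * F_t, m12 * F_c + m22 * F_t


# ---------------------------------------------------------------------------
# FA / SF stochastic maintenance


def update_fas(cell: CellBody, network: FiberNetwork, cfg: CellConfig,
               motor: MotorBindingConfig, dt: float, rng: np.random.Generator,
               candidate_segs: dict[int, np.ndarray] | None = None) -> None:
    """Advance FA bond populations: Bell rupture (k_off0 scaled for the
    slower FA turnover), Monte-Carlo binding against the local ligand pool,
    creation at membrane nodes near a fiber, geometric detachment, and
    stress-fiber nucleation/removal at the SF maturity threshold."""
    # rupture + rebinding of existing FAs
    for node in list(cell.fas):
        fa = cell.fas[node]
        na, nb = network.segments[fa.seg_id]
        if not network.seg_active[fa.seg_id]:
            _drop_fa(cell, network, node)
            continue
        anchor = (1 - fa.s) * network.positions[na] + fa.s * network.positions[nb]
        L = float(np.linalg.norm(anchor - cell.x_c[node]))
        if L > cfg.fa_detach_distance_um:
            _drop_fa(cell, network, node)
            continue
        ext = max(L - motor.lambda_um, 0.0)
        k_off = cfg.fa_koff0_scale * bell_koff(ext, motor)
        p_off = 1.0 - math.exp(-k_off * dt)
        lost = int(rng.binomial(fa.n_b, p_off)) if fa.n_b else 0
        fa.n_b -= lost
        network.ligand_bound[fa.ligand_node] -= lost
        free_lig = int(network.ligand_capacity[fa.ligand_node]
                       - network.ligand_bound[fa.ligand_node])
        p_on = binding_probability(free_lig, dt, motor)
        free_rec = max(cfg.fa_bond_cap - fa.n_b, 0)
        add = min(int(rng.binomial(free_rec, p_on)) if free_rec else 0, free_lig)
        fa.n_b += add
        network.ligand_bound[fa.ligand_node] += add
        if fa.n_b == 0 and rng.random() < 0.5:
            _drop_fa(cell, network, node)
    # creation at FA-free membrane nodes with a nearby fiber
    if candidate_segs is not None:
        nodes = candidate_segs.keys()
    else:
        nodes = range(cell.n_nodes)
    for node in nodes:
        if node in cell.fas:
            continue
        segs = candidate_segs[node] if candidate_segs is not None else None
        fa = _find_fa_anchor(cell.x_c[node], network, cfg, segs)
        if fa is not None:
            fa.node = node
            cell.fas[node] = fa
    # stress fibers follow FA maturity
    for node, fa in cell.fas.items():
        if fa.n_b >= cfg.sf_maturity_bonds and node not in cell.sfs:
            n_node = int(np.argmin(
                np.linalg.norm(cell.x_n - cell.x_t[node], axis=1)))
            rest = float(np.linalg.norm(cell.x_n[n_node] - cell.x_t[node]))
            cell.sfs[node] = StressFiber(t_node=node, n_node=n_node, rest=rest)
    for node in list(cell.sfs):
        if node not in cell.fas:
            del cell.sfs[node]


def update_sfs(cell: CellBody, motor: MotorBindingConfig, dt: float) -> None:
    """SF contraction: rest length shortens at 2·v_m under its own tension."""
    for sf in cell.sfs.values():
        d = cell.x_n[sf.n_node] - cell.x_t[sf.t_node]
        L = float(np.linalg.norm(d))
        kappa = float(am_stiffness(sf.rest, motor))
        tension = max(kappa * (L - sf.rest), 0.0)
        v_m = myosin_velocity(min(tension, motor.f_stall_pn), motor)
        sf.rest = max(sf.rest - 2.0 * v_m * dt, 0.1)


def _drop_fa(cell: CellBody, network: FiberNetwork, node: int) -> None:
    fa = cell.fas.pop(node)
    network.ligand_bound[fa.ligand_node] -= fa.n_b


def _find_fa_anchor(x: np.ndarray, network: FiberNetwork, cfg: CellConfig,
                    seg_ids: np.ndarray | None) -> FocalAdhesion | None:
    if seg_ids is None:
        seg_ids = np.where(network.seg_active)[0]
    else:
        seg_ids = np.asarray(seg_ids)
        if seg_ids.size:
            seg_ids = seg_ids[network.seg_active[seg_ids]]
    if seg_ids.size == 0:
        return None
    a = network.positions[network.segments[seg_ids, 0]]
    b = network.positions[network.segments[seg_ids, 1]]
    e = b - a
    ee = (e * e).sum(axis=1)
    t = np.clip(((x - a) * e).sum(axis=1) / np.where(ee > 0, ee, 1.0), 0, 1)
    closest = a + t[:, None] * e
    dist = np.linalg.norm(closest - x, axis=1)
    best = int(np.lexsort((seg_ids, np.round(dist, 12)))[0])
    if dist[best] >= cfg.fa_range_um:
        return None
    sid = int(seg_ids[best])
    na, nb = network.segments[sid]
    s = float(t[best])
    if network.ligand_capacity[na] == 0 and network.ligand_capacity[nb] > 0:
        lig = int(nb)
    elif network.ligand_capacity[nb] == 0 and network.ligand_capacity[na] > 0:
        lig = int(na)
    else:
        lig = int(na if s <= 0.5 else nb)
    return FocalAdhesion(node=-1, seg_id=sid, s=s, ligand_node=lig, n_b=0)


def update_polarization(cell: CellBody, displacement: np.ndarray,
                        cfg: CellConfig) -> None:
    """Exponential moving average of the recent centroid displacement
    direction."""
    norm = np.linalg.norm(displacement)
    if norm < 1e-12:
        return
    target = displacement / norm
    p = (1 - cfg.polarization_ema) * cell.polarization + cfg.polarization_ema * target
    cell.polarization = p / np.linalg.norm(p)


__all__ = [
    "CellBody",
    "FocalAdhesion",
    "StressFiber",
    "build_cell",
    "fibonacci_sphere",
    "enclosed_volume",
    "volume_gradient",
    "edge_spring_forces",
    "volume_penalty_forces",
    "cortex_forces",
    "lamellipodium_forces",
    "fa_forces",
    "membrane_forces",
    "nucleus_sf_forces",
    "coupled_membrane_cortex_rates",
    "update_fas",
    "update_sfs",
    "update_polarization",
]
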