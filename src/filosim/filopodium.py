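"""Single-filopodium penetration dynamics.

A filopodium is a chain of nodes spanned by N_AM = 8 contractile acto-myosin
(AM) compartments; the first compartment is rooted at a cell-membrane node
and the last ends at the tip.  The tip carries at most one focal complex
(FC): a stochastic cluster of integrin–ligand bonds to the nearest fiber
segment, formed only while the tip-to-fiber gap is below 100 nm, loaded as a
shared linear spring (κ_LR = 1 pN/nm, rest length λ = 30 nm) and ruptured by
Bell slip-bond kinetics.  Myosin sliding follows the whole-muscle
force–velocity law v_m = v_m0 (F_stall − F)/(F_stall + c_m F) and shortens
every compartment's rest length at 2·v_m.

Phases (seven-state machine): 0 inactive, 1 active, 2 outgrowing, 3 tugging,
4 contractile, 5 retractile, 6 decay.  Outgrowing switches to tugging when an
FC forms within the phase's time budget; the rupture test (all bonds lost)
sends tugging back to outgrowing; the tugging tip tension crossing the
contractile threshold enters the contractile phase; lengths are clamped to
[L_min, L_max] = [2, 4.5] μm by the retractile/decay branches.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .config import MotorBindingConfig
from .network import FiberNetwork

MotorAndBindingParams = MotorBindingConfig  # canonical parameter bundle


class FiloState(enum.IntEnum):
    INACTIVE = 0
    ACTIVE = 1
    OUTGROWING = 2
    TUGGING = 3
    CONTRACTILE = 4
    RETRACTILE = 5
    DECAY = 6


@dataclass
class FocalComplex:
    """Bond cluster anchoring a filopodial tip to a fiber segment."""

    seg_id: int
    chain_id: int
    s: float                       # parametric anchor position in [0, 1]
    ligand_node: int               # fiber node whose ligand pool is used
    n_b: int = 0
    h_p: float = 0.0               # gap, μm
    L_b: float = 0.0               # stretched bond length, μm
    n_w: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_R: np.ndarray = field(default_factory=lambda: np.zeros(3))
    x_L: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def extension(self, lam: float) -> float:
        """Bond extension beyond rest; compression counts as zero."""
        return max(self.L_b - lam, 0.0)


@dataclass
class Filopodium:
    """Node chain + AM compartments + phase state of one filopodium."""

    positions: np.ndarray           # (n_am + 1, 3); row 0 is the root
    am_rest: np.ndarray             # (n_am,) rest lengths L_AM¹, μm
    growth_axis: np.ndarray         # unit vector N_filo
    state: FiloState = FiloState.ACTIVE
    t_in_state: float = 0.0
    fc: FocalComplex | None = None
    root_membrane_node: int = -1
    tension: float = 0.0            # |F_FC| at the tip, pN

    @property
    def n_am(self) -> int:
        return self.am_rest.shape[0]

    @property
    def tip(self) -> np.ndarray:
        return self.positions[-1]

    def length(self) -> float:
        d = np.diff(self.positions, axis=0)
        return float(np.linalg.norm(d, axis=1).sum())

    def spans(self) -> np.ndarray:
        """Current compartment spans d_AM,j."""
        d = np.diff(self.positions, axis=0)
        return np.linalg.norm(d, axis=1)


def make_filopodium(root: np.ndarray, axis: np.ndarray,
                    params: MotorAndBindingParams,
                    length: float | None = None,
                    root_membrane_node: int = -1) -> Filopodium:
    """Straight filopodium of ``length`` (default L_min) along ``axis``."""
    L = params.l_min_um if length is None else length
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    n = params.n_am
    ts = np.linspace(0.0, L, n + 1)
    pos = np.asarray(root, dtype=float)[None, :] + ts[:, None] * axis[None, :]
    return Filopodium(
        positions=pos,
        am_rest=np.full(n, L / n),
        growth_axis=axis,
        state=FiloState.OUTGROWING,
        root_membrane_node=root_membrane_node,
    )


# ---------------------------------------------------------------------------
# motor law


def myosin_velocity(f_tr_pn: float, params: MotorAndBindingParams) -> float:
    """Myosin II sliding rate (μm/s) under load; zero at/beyond stall."""
    if f_tr_pn < 0:
        raise ValueError("load must be non-negative")
    if f_tr_pn >= params.f_stall_pn:
        return 0.0
    return params.v_m0_um_s * (params.f_stall_pn - f_tr_pn) / (
        params.f_stall_pn + params.c_m * f_tr_pn
    )


def am_stiffness(rest_um: np.ndarray | float, params: MotorAndBindingParams):
    """κ_AM = E_AM·A_AM / L_AM¹, pN/μm."""
    return params.e_am_pa * params.a_am_um2 / np.asarray(rest_um, dtype=float)


def am_update_and_forces(filo: Filopodium, f_tr_pn: float, dt: float,
                         params: MotorAndBindingParams):
    """Shorten every compartment rest length at 2·v_m and return the nodal
    contraction forces (−∂H_AM/∂x via the virtual-work expression).

    Rest lengths are floored at ``am_rest_floor_um``.  Returns the
    (n_am + 1, 3) per-node force array.
    """
    v_m = myosin_velocity(f_tr_pn, params)
    filo.am_rest -= 2.0 * v_m * dt
    np.clip(filo.am_rest, params.am_rest_floor_um, None, out=filo.am_rest)
    return am_forces(filo, params)


def am_grow(filo: Filopodium, dt: float, params: MotorAndBindingParams) -> None:
    """Polymerization growth: total rest length extends at ``v_poly``,
    distributed over the compartments (outgrowing phase only)."""
    filo.am_rest += params.v_poly_um_s * dt / filo.n_am


def am_forces(filo: Filopodium, params: MotorAndBindingParams) -> np.ndarray:
    """Nodal forces of the AM compartment springs, κ_j (d_j − L¹_j)."""
    d = np.diff(filo.positions, axis=0)
    spans = np.linalg.norm(d, axis=1)
    spans = np.where(spans < 1e-12, 1e-12, spans)
    unit = d / spans[:, None]
    kappa = am_stiffness(filo.am_rest, params)
    tension = kappa * (spans - filo.am_rest)          # >0 when stretched
    F = np.zeros_like(filo.positions)
    # compartment j pulls its lower node (+) and upper node (−) when stretched
    np.add.at(F, np.arange(filo.n_am), tension[:, None] * unit)
    np.add.at(F, np.arange(1, filo.n_am + 1), -tension[:, None] * unit)
    return F


# ---------------------------------------------------------------------------
# protrusion


def protrusion_force(grad_vegf: np.ndarray, state: FiloState,
                     growth_axis: np.ndarray,
                     params: MotorAndBindingParams) -> np.ndarray:
    """F_P = F_P,max · n̂_VEGF at the tip, outgrowing phase only.

    A vanishing VEGF gradient falls back to the current growth axis.
    """
    if state != FiloState.OUTGROWING:
        return np.zeros(3)
    g = np.asarray(grad_vegf, dtype=float)
    norm = np.linalg.norm(g)
    if norm < 1e-30:
        direction = growth_axis / np.linalg.norm(growth_axis)
    else:
        direction = g / norm
    return params.f_p_max_pn * direction


# ---------------------------------------------------------------------------
# focal-complex geometry


def anchor_geometry(tip: np.ndarray, a: np.ndarray, b: np.ndarray):
    """(s, x_L, h_p, L_b, n_w, n_R) for a tip against segment a–b.

    ``x_L`` is the closest point of the segment (the bond-root location),
    ``h_p`` the tip-to-axis gap, ``n_w`` the outward fiber-surface normal at
    the tip (triple cross product (b−a)×((tip−a)×(b−a)), normalized) and
    ``n_R`` the unit bond direction from the tip toward ``x_L``.
    """
    e = b - a
    ee = float(np.dot(e, e))
    p = tip - a
    t_raw = float(np.dot(p, e)) / ee if ee > 0 else 0.0
    s = min(max(t_raw, 0.0), 1.0)
    x_L = a + s * e
    d = x_L - tip
    L_b = float(np.linalg.norm(d))
    # perpendicular (axis) gap and surface normal
    perp = p - t_raw * e
    h_p = float(np.linalg.norm(perp))
    if h_p < 1e-9:
        # tip numerically on the fiber axis: perturb to define the normal
        perp = perp + 1e-6
        h_p = float(np.linalg.norm(perp))
    n_w = perp / h_p
    if L_b > 1e-12:
        n_R = d / L_b
    else:
        n_R = -n_w
    return s, x_L, h_p, L_b, n_w, n_R


def candidate_anchor(tip: np.ndarray, network: FiberNetwork,
                     params: MotorAndBindingParams,
                     seg_ids: np.ndarray | None = None) -> FocalComplex | None:
    """Nearest active fiber segment within the 100 nm formation gate.

    Ties between equidistant segments break deterministically toward the
    lowest (chain id, segment id).  Returns an (unbonded) FocalComplex or
    None when no segment lies within the gate.
    """
    tip = np.asarray(tip, dtype=float)
    if seg_ids is None:
        seg_ids = np.where(network.seg_active)[0]
    else:
        seg_ids = np.asarray(seg_ids)
        seg_ids = seg_ids[network.seg_active[seg_ids]]
    if seg_ids.size == 0:
        return None
    a = network.positions[network.segments[seg_ids, 0]]
    b = network.positions[network.segments[seg_ids, 1]]
    e = b - a
    ee = (e * e).sum(axis=1)
    p = tip[None, :] - a
    t = np.clip((p * e).sum(axis=1) / np.where(ee > 0, ee, 1.0), 0.0, 1.0)
    closest = a + t[:, None] * e
    dist = np.linalg.norm(closest - tip[None, :], axis=1)
    order = np.lexsort((seg_ids, network.seg_chain[seg_ids], np.round(dist, 12)))
    best = order[0]
    if dist[best] >= params.contact_range_um:
        return None
    sid = int(seg_ids[best])
    na, nb = network.segments[sid]
    s, x_L, h_p, L_b, n_w, n_R = anchor_geometry(
        tip, network.positions[na], network.positions[nb]
    )
    if h_p >= params.contact_range_um and L_b >= params.contact_range_um:
        return None
    # ligand pool lives at the nearer fiber end node (crosslink nodes carry none)
    if network.ligand_capacity[na] == 0 and network.ligand_capacity[nb] > 0:
        ligand_node = int(nb)
    elif network.ligand_capacity[nb] == 0 and network.ligand_capacity[na] > 0:
        ligand_node = int(na)
    else:
        ligand_node = int(na if s <= 0.5 else nb)
    return FocalComplex(
        seg_id=sid, chain_id=int(network.seg_chain[sid]), s=s,
        ligand_node=ligand_node, n_b=0, h_p=h_p, L_b=L_b,
        n_w=n_w, n_R=n_R, x_L=x_L,
    )


def reproject_anchor(fc: FocalComplex, tip: np.ndarray,
                     network: FiberNetwork) -> None:
    """Slide the anchor to the closest point of its segment (tip crawling is
    emergent: the binding site migrates along the fiber as forces evolve)."""
    na, nb = network.segments[fc.seg_id]
    s, x_L, h_p, L_b, n_w, n_R = anchor_geometry(
        np.asarray(tip, dtype=float), network.positions[na], network.positions[nb]
    )
    fc.s, fc.x_L, fc.h_p, fc.L_b, fc.n_w, fc.n_R = s, x_L, h_p, L_b, n_w, n_R


# ---------------------------------------------------------------------------
# stochastic bond kinetics


def binding_probability(free_ligands: int, dt: float,
                        params: MotorAndBindingParams) -> float:
    """p_b = 1 − exp(−k_on Δt) with k_on = k_f · (C_L − C_b) per receptor."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    k_on = params.k_f * max(free_ligands, 0)
    return 1.0 - math.exp(-k_on * dt)


def sample_bond_formation(fc: FocalComplex, network: FiberNetwork, dt: float,
                          rng: np.random.Generator,
                          params: MotorAndBindingParams) -> int:
    """Monte-Carlo binding of free receptors to the local free-ligand pool.

    Returns the number of bonds added; the node's bound-ligand count is
    updated and never exceeds capacity.
    """
    node = fc.ligand_node
    free_ligands = int(network.ligand_capacity[node] - network.ligand_bound[node])
    p_b = binding_probability(free_ligands, dt, params)
    free_receptors = max(params.n_receptors - fc.n_b, 0)
    added = int(rng.binomial(free_receptors, p_b)) if free_receptors else 0
    added = min(added, free_ligands)
    fc.n_b += added
    network.ligand_bound[node] += added
    return added


def bell_koff(extension_um: float, params: MotorAndBindingParams) -> float:
    """Bell slip-bond dissociation rate, k_off0·exp(κ_LR·ΔL·x_b / k_bT)."""
    ext = max(extension_um, 0.0)
    expo = params.kappa_lr_pn_um * ext * params.x_b_um / params.kt_pn_um
    return params.k_off0 * math.exp(expo)


def sample_bond_rupture(fc: FocalComplex, network: FiberNetwork, dt: float,
                        rng: np.random.Generator,
                        params: MotorAndBindingParams) -> int:
    """Monte-Carlo rupture; ruptured ligands return to the free pool.

    Returns the surviving bond count.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if fc.n_b == 0:
        return 0
    k_off = bell_koff(fc.extension(params.lambda_um), params)
    p = 1.0 - math.exp(-k_off * dt)
    lost = int(rng.binomial(fc.n_b, p))
    fc.n_b -= lost
    network.ligand_bound[fc.ligand_node] -= lost
    return fc.n_b


def release_fc(fc: FocalComplex, network: FiberNetwork) -> None:
    """Return all bound ligands of this FC to the free pool."""
    network.ligand_bound[fc.ligand_node] -= fc.n_b
    fc.n_b = 0


# ---------------------------------------------------------------------------
# FC force


def fc_force(fc: FocalComplex, params: MotorAndBindingParams):
    """(force on the filopodial tip, forces on the two anchor end nodes).

    F = n_b·κ_LR·(L_b − λ)·n̂_R on the tip; the exact opposite load is
    split between the segment ends by linear interpolation at the anchor's
    parametric position, so the pair sums to zero.
    """
    F_tip = fc.n_b * params.kappa_lr_pn_um * (fc.L_b - params.lambda_um) * fc.n_R
    F_a = -F_tip * (1.0 - fc.s)
    F_b = -F_tip - F_a          # exact action–reaction in floating point
    return F_tip, F_a, F_b


# ---------------------------------------------------------------------------
# state machine


def advance_state(filo: Filopodium, dt: float,
                  params: MotorAndBindingParams) -> FiloState:
    """One tick of the phase machine; timers reset on every transition.

    The caller keeps ``filo.fc`` and ``filo.tension`` current.  Entry actions
    (clearing the FC on retraction, removing the filopodium on decay) belong
    to the engine.
    """
    s = filo.state
    L = filo.length()
    bonds = filo.fc.n_b if filo.fc is not None else 0
    new = s
    if s == FiloState.ACTIVE:
        new = FiloState.OUTGROWING
    elif s == FiloState.OUTGROWING:
        if bonds > 0:
            new = FiloState.TUGGING
        elif L >= params.l_max_um or filo.t_in_state > params.outgrow_budget_s:
            new = FiloState.RETRACTILE
    elif s == FiloState.TUGGING:
        if bonds == 0:
            new = FiloState.OUTGROWING          # rupture test failed
        elif filo.tension >= params.contractile_threshold_pn:
            new = FiloState.CONTRACTILE
        elif filo.t_in_state > params.tugging_budget_s:
            new = FiloState.RETRACTILE          # weak traction
    elif s == FiloState.CONTRACTILE:
        if bonds == 0:
            new = FiloState.OUTGROWING
        elif filo.t_in_state > params.contractile_budget_s:
            new = FiloState.RETRACTILE
    elif s == FiloState.RETRACTILE:
        if L <= params.l_min_um:
            new = FiloState.DECAY
    elif s == FiloState.DECAY:
        new = FiloState.INACTIVE
    elif s != FiloState.INACTIVE:
        raise ValueError(f"unknown filopodium state {s!r}")
    if new != s:
        filo.state = new
        filo.t_in_state = 0.0
    else:
        filo.t_in_state += dt
    return filo.state


# ---------------------------------------------------------------------------
# trajectory statistic


def mean_speed(times: np.ndarray, positions: np.ndarray,
               t0: float, tf: float) -> float:
    """Time-averaged tip speed: path length of successive displacements in
    [t0, tf] divided by (tf − t0)."""
    if tf <= t0:
        raise ValueError("tf must exceed t0")
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    mask = (times >= t0 - 1e-12) & (times <= tf + 1e-12)
    if mask.sum() < 2:
        raise ValueError("need at least two samples inside [t0, tf]")
    p = positions[mask]
    steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return float(steps.sum() / (tf - t0))


__all__ = [
    "FiloState",
    "Filopodium",
    "FocalComplex",
    "MotorAndBindingParams",
    "make_filopodium",
    "myosin_velocity",
    "am_stiffness",
    "am_update_and_forces",
    "am_grow",
    "am_forces",
    "protrusion_force",
    "anchor_geometry",
    "candidate_anchor",
    "reproject_anchor",
    "binding_probability",
    "sample_bond_formation",
    "bell_koff",
    "sample_bond_rupture",
    "release_fc",
    "fc_force",
    "advance_state",
    "mean_speed",
]
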