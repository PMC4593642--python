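"""Procedural generation, storage and degradation of cross-linked ECM fiber
networks.

The generator replaces the original CAD/CFD meshing pipeline with a
reproducible procedure: crosslink seed points are placed on a jittered cubic
lattice at the target pore spacing, candidate fibers are the short edges of
the Delaunay tetrahedralization of those seeds, and each crosslink-to-crosslink
line is split into ``n_div`` fiber segments plus two 30 nm crosslink segments
carrying ``n_div + 1`` fiber nodes.  Segment sets that continue nearly
collinearly through a crosslink are joined into extended fibers
("coaxial joining": the chain continues when the bend away from straight is
below 60°).  Each incident fiber end is crosslinked independently with
probability ``p_f`` (0.7 by default); un-crosslinked ends remain free.

Degradation is driven by the local ECM integrity ``I = C_ECM / C_ECM0``:
the number of detached fibers at a crosslink node is
``N_uf = round((1 - I) · N_0f)`` and detachment (removal of the 30 nm
crosslink-segment coupling) is monotone — crosslinks never re-form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .config import NetworkConfig, default_n_div

NODE_CROSSLINK = 0
NODE_FIBER = 1

SEG_FIBER = 0
SEG_CROSSLINK = 1


class NetworkSizingError(ValueError):
    """Domain too small for the requested pore size."""


@dataclass
class NetworkParams:
    """Validated generation parameters (thin wrapper over NetworkConfig)."""

    pore_size_um: float
    fiber_diameter_nm: float
    n_div: int
    crosslink_segment_um: float = 0.03
    p_f: float = 0.7
    ligand_capacity: int = 300
    domain_um: tuple[float, float, float] = (10.0, 10.0, 10.0)
    seed: int | None = None
    jitter: float = 0.12
    edge_cutoff_factor: float = 1.45
    ecm_conc0_m: float = 10e-6
    continuation_angle_deg: float = 60.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("NetworkParams.seed is required (determinism)")
        if self.pore_size_um <= 2 * self.crosslink_segment_um:
            raise ValueError("pore size must exceed twice the crosslink segment length")
        if self.n_div < 1:
            raise ValueError("n_div must be >= 1")
        if not 0.0 <= self.p_f <= 1.0:
            raise ValueError("p_f must lie in [0, 1]")
        if self.ligand_capacity <= 0:
            raise ValueError("ligand_capacity must be positive")
        if min(self.domain_um) < 3 * self.pore_size_um:
            raise NetworkSizingError(
                f"domain {self.domain_um} too small: each extent must be >= "
                f"3 × pore size ({3 * self.pore_size_um} μm)"
            )

    @classmethod
    def from_config(
        cls, net: NetworkConfig, fiber_diameter_nm: float, seed: int
    ) -> "NetworkParams":
        n_div = net.n_div if net.n_div is not None else default_n_div(net.pore_size_um)
        return cls(
            pore_size_um=net.pore_size_um,
            fiber_diameter_nm=fiber_diameter_nm,
            n_div=n_div,
            crosslink_segment_um=net.crosslink_segment_um,
            p_f=net.p_f,
            ligand_capacity=net.ligand_capacity,
            domain_um=tuple(net.domain_um),
            seed=seed,
            jitter=net.jitter,
            edge_cutoff_factor=net.edge_cutoff_factor,
            ecm_conc0_m=net.ecm_conc0_m,
            continuation_angle_deg=net.continuation_angle_deg,
        )


@dataclass
class FiberNetwork:
    """Geometry, connectivity and chemical bookkeeping of a fiber network.

    Arrays use the package unit system (μm, pN, s, M).  ``seg_active`` marks
    couplings that still exist; degraded crosslink segments are deactivated
    in place so node count and chain membership never change.
    """

    positions: np.ndarray          # (N, 3) float64, μm
    node_type: np.ndarray          # (N,) uint8: crosslink | fiber
    segments: np.ndarray           # (M, 2) int32 node ids
    seg_L0: np.ndarray             # (M,) rest lengths, μm
    seg_kind: np.ndarray           # (M,) uint8: fiber | crosslink segment
    seg_chain: np.ndarray          # (M,) int32 owning chain (fiber) id
    seg_active: np.ndarray         # (M,) bool
    chains: list[np.ndarray]       # ordered node lists per extended fiber
    triples: np.ndarray            # (K, 3) int32 bend triples (a, b, c)
    tri_th0: np.ndarray            # (K,) rest angles, rad (0 = straight)
    tri_L0: np.ndarray             # (K,) normalization lengths, μm
    tri_segs: np.ndarray           # (K, 2) int32 segment ids forming the bend
    xl_nodes: np.ndarray           # crosslink node ids
    xl_seg_ptr: np.ndarray         # CSR pointers into xl_seg_ids
    xl_seg_ids: np.ndarray         # crosslink-segment ids incident per xl node
    n_ifs: np.ndarray              # linkable fiber ends per crosslink node
    n_f0: np.ndarray               # initially crosslinked count
    n_uf: np.ndarray               # detached (uncrosslinked) so far
    ligand_capacity: np.ndarray    # (N,) C_L per node (0 at crosslink nodes)
    ligand_bound: np.ndarray       # (N,) C_b
    ecm_conc: np.ndarray           # (N,) C_ECM, M
    ecm_conc0: float               # C_ECM0, M
    domain_um: tuple[float, float, float]
    params: NetworkParams | None = None
    _tri_active_cache: np.ndarray | None = field(default=None, repr=False)

    # -- derived -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    def integrity(self) -> np.ndarray:
        """Local ECM integrity I = C_ECM / C_ECM0 ∈ [0, 1] per node."""
        return np.clip(self.ecm_conc / self.ecm_conc0, 0.0, 1.0)

    def tri_active(self) -> np.ndarray:
        """A bend triple acts only while both of its segments are active."""
        return self.seg_active[self.tri_segs[:, 0]] & self.seg_active[self.tri_segs[:, 1]]

    def segment_lengths(self) -> np.ndarray:
        d = self.positions[self.segments[:, 1]] - self.positions[self.segments[:, 0]]
        return np.linalg.norm(d, axis=1)

    def mean_crosslink_spacing(self) -> float:
        """Mean nearest-neighbour distance among crosslink nodes."""
        pts = self.positions[self.node_type == NODE_CROSSLINK]
        tree = cKDTree(pts)
        dist, _ = tree.query(pts, k=2)
        return float(dist[:, 1].mean())

    def boundary_sets(self, axis: int = 0, tol: float | None = None):
        """Node ids on the two opposing domain faces along ``axis``."""
        x = self.positions[:, axis]
        if tol is None:
            tol = 0.5 * (self.params.pore_size_um if self.params else 0.5)
        lo = np.where(x <= x.min() + tol)[0]
        hi = np.where(x >= x.max() - tol)[0]
        return lo, hi

    def copy(self) -> "FiberNetwork":
        return FiberNetwork(
            positions=self.positions.copy(),
            node_type=self.node_type.copy(),
            segments=self.segments.copy(),
            seg_L0=self.seg_L0.copy(),
            seg_kind=self.seg_kind.copy(),
            seg_chain=self.seg_chain.copy(),
            seg_active=self.seg_active.copy(),
            chains=[c.copy() for c in self.chains],
            triples=self.triples.copy(),
            tri_th0=self.tri_th0.copy(),
            tri_L0=self.tri_L0.copy(),
            tri_segs=self.tri_segs.copy(),
            xl_nodes=self.xl_nodes.copy(),
            xl_seg_ptr=self.xl_seg_ptr.copy(),
            xl_seg_ids=self.xl_seg_ids.copy(),
            n_ifs=self.n_ifs.copy(),
            n_f0=self.n_f0.copy(),
            n_uf=self.n_uf.copy(),
            ligand_capacity=self.ligand_capacity.copy(),
            ligand_bound=self.ligand_bound.copy(),
            ecm_conc=self.ecm_conc.copy(),
            ecm_conc0=self.ecm_conc0,
            domain_um=self.domain_um,
            params=self.params,
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "node_type": self.node_type.tolist(),
            "segments": self.segments.tolist(),
            "seg_L0": self.seg_L0.tolist(),
            "seg_kind": self.seg_kind.tolist(),
            "seg_chain": self.seg_chain.tolist(),
            "seg_active": self.seg_active.tolist(),
            "chains": [c.tolist() for c in self.chains],
            "triples": self.triples.tolist(),
            "tri_th0": self.tri_th0.tolist(),
            "tri_L0": self.tri_L0.tolist(),
            "tri_segs": self.tri_segs.tolist(),
            "xl_nodes": self.xl_nodes.tolist(),
            "xl_seg_ptr": self.xl_seg_ptr.tolist(),
            "xl_seg_ids": self.xl_seg_ids.tolist(),
            "n_ifs": self.n_ifs.tolist(),
            "n_f0": self.n_f0.tolist(),
            "n_uf": self.n_uf.tolist(),
            "ligand_capacity": self.ligand_capacity.tolist(),
            "ligand_bound": self.ligand_bound.tolist(),
            "ecm_conc": self.ecm_conc.tolist(),
            "ecm_conc0": self.ecm_conc0,
            "domain_um": list(self.domain_um),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiberNetwork":
        return cls(
            positions=np.asarray(d["positions"], dtype=np.float64),
            node_type=np.asarray(d["node_type"], dtype=np.uint8),
            segments=np.asarray(d["segments"], dtype=np.int32),
            seg_L0=np.asarray(d["seg_L0"], dtype=np.float64),
            seg_kind=np.asarray(d["seg_kind"], dtype=np.uint8),
            seg_chain=np.asarray(d["seg_chain"], dtype=np.int32),
            seg_active=np.asarray(d["seg_active"], dtype=bool),
            chains=[np.asarray(c, dtype=np.int32) for c in d["chains"]],
            triples=np.asarray(d["triples"], dtype=np.int32).reshape(-1, 3),
            tri_th0=np.asarray(d["tri_th0"], dtype=np.float64),
            tri_L0=np.asarray(d["tri_L0"], dtype=np.float64),
            tri_segs=np.asarray(d["tri_segs"], dtype=np.int32).reshape(-1, 2),
            xl_nodes=np.asarray(d["xl_nodes"], dtype=np.int32),
            xl_seg_ptr=np.asarray(d["xl_seg_ptr"], dtype=np.int64),
            xl_seg_ids=np.asarray(d["xl_seg_ids"], dtype=np.int32),
            n_ifs=np.asarray(d["n_ifs"], dtype=np.int32),
            n_f0=np.asarray(d["n_f0"], dtype=np.int32),
            n_uf=np.asarray(d["n_uf"], dtype=np.int32),
            ligand_capacity=np.asarray(d["ligand_capacity"], dtype=np.int64),
            ligand_bound=np.asarray(d["ligand_bound"], dtype=np.int64),
            ecm_conc=np.asarray(d["ecm_conc"], dtype=np.float64),
            ecm_conc0=float(d["ecm_conc0"]),
            domain_um=tuple(d["domain_um"]),
        )


# ---------------------------------------------------------------------------
# generation


def build_network(params: NetworkParams) -> FiberNetwork:
    """Generate a cross-linked fiber network with controlled pore size.

    The returned network's mean nearest-crosslink spacing tracks
    ``params.pore_size_um`` (within ~10% for the default jitter), every
    fiber node carries the full ligand capacity and the initial ECM
    concentration, and construction is bit-deterministic for a fixed
    (params, seed) pair.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(params.seed)))
    a = params.pore_size_um
    dx, dy, dz = params.domain_um

    # jittered-lattice crosslink seeds
    nx, ny, nz = (max(2, int(round(d / a)) + 1) for d in (dx, dy, dz))
    gx, gy, gz = np.meshgrid(
        np.arange(nx) * a, np.arange(ny) * a, np.arange(nz) * a, indexing="ij"
    )
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(np.float64)
    pts += rng.uniform(-params.jitter * a, params.jitter * a, size=pts.shape)

    # candidate fibers: short Delaunay edges
    tri = Delaunay(pts)
    edges = set()
    for simplex in tri.simplices:
        s = np.sort(simplex)
        for i in range(4):
            for j in range(i + 1, 4):
                edges.add((int(s[i]), int(s[j])))
    edges = np.array(sorted(edges), dtype=np.int64)
    elen = np.linalg.norm(pts[edges[:, 1]] - pts[edges[:, 0]], axis=1)
    keep = elen <= params.edge_cutoff_factor * a
    edges, elen = edges[keep], elen[keep]

    n_xl = pts.shape[0]
    n_div = params.n_div
    cl = params.crosslink_segment_um

    # nodes: crosslink nodes first, then per-edge fiber nodes
    positions = [pts]
    node_type = [np.full(n_xl, NODE_CROSSLINK, dtype=np.uint8)]
    seg_i, seg_j, seg_kind = [], [], []
    # bookkeeping per edge: fiber-node index range, crosslink-segment ids at
    # each end (or -1 when the end was left uncrosslinked)
    edge_first_fn = np.empty(len(edges), dtype=np.int64)
    edge_first_fseg = np.empty(len(edges), dtype=np.int64)
    edge_xl_seg = np.full((len(edges), 2), -1, dtype=np.int64)
    crosslinked = rng.random((len(edges), 2)) < params.p_f

    next_node = n_xl
    for e, (u, v) in enumerate(edges):
        L = elen[e]
        # fiber nodes along the edge: first at 30 nm from u, last 30 nm from v
        ts = cl + (L - 2 * cl) * np.arange(n_div + 1) / n_div
        direction = (pts[v] - pts[u]) / L
        fn_pos = pts[u][None, :] + ts[:, None] * direction[None, :]
        positions.append(fn_pos)
        node_type.append(np.full(n_div + 1, NODE_FIBER, dtype=np.uint8))
        ids = np.arange(next_node, next_node + n_div + 1)
        edge_first_fn[e] = next_node
        next_node += n_div + 1
        # crosslink segment at the u end
        if crosslinked[e, 0]:
            edge_xl_seg[e, 0] = len(seg_i)
            seg_i.append(u)
            seg_j.append(ids[0])
            seg_kind.append(SEG_CROSSLINK)
        # fiber segments
        edge_first_fseg[e] = len(seg_i)
        for k in range(n_div):
            seg_i.append(ids[k])
            seg_j.append(ids[k + 1])
            seg_kind.append(SEG_FIBER)
        # crosslink segment at the v end
        if crosslinked[e, 1]:
            edge_xl_seg[e, 1] = len(seg_i)
            seg_i.append(ids[-1])
            seg_j.append(v)
            seg_kind.append(SEG_CROSSLINK)

    positions = np.concatenate(positions, axis=0)
    node_type = np.concatenate(node_type)
    segments = np.column_stack([seg_i, seg_j]).astype(np.int32)
    seg_kind = np.asarray(seg_kind, dtype=np.uint8)
    seg_L0 = np.linalg.norm(
        positions[segments[:, 1]] - positions[segments[:, 0]], axis=1
    )

    # coaxial joining: pair edges through shared crosslink nodes when the bend
    # away from straight continuation is below the threshold
    chains_edges = _join_coaxial(
        pts, edges, elen, crosslinked, params.continuation_angle_deg, rng
    )

    # express chains as node sequences and derive bend triples
    seg_chain = np.full(len(segments), -1, dtype=np.int32)
    chains: list[np.ndarray] = []
    triples, tri_segs = [], []
    edge_seg_ids = _edge_segment_ids(edges, edge_xl_seg, edge_first_fseg, n_div)

    for cid, chain in enumerate(chains_edges):
        nodes_seq: list[int] = []
        segs_seq: list[int] = []
        for (e, forward) in chain:
            u, v = edges[e]
            ids = list(range(edge_first_fn[e], edge_first_fn[e] + n_div + 1))
            enodes = [int(u)] + ids + [int(v)]
            esegs = edge_seg_ids[e]
            if not forward:
                enodes = enodes[::-1]
                esegs = esegs[::-1]
            if nodes_seq:
                # shared crosslink node already present
                enodes = enodes[1:]
            nodes_seq.extend(enodes)
            segs_seq.extend(esegs)
        chains.append(np.asarray(nodes_seq, dtype=np.int32))
        for s in segs_seq:
            if s >= 0:
                seg_chain[s] = cid
        # interior bend triples: need both flanking segments present
        for k in range(1, len(nodes_seq) - 1):
            s1, s2 = segs_seq[k - 1], segs_seq[k]
            if s1 < 0 or s2 < 0:
                continue
            triples.append((nodes_seq[k - 1], nodes_seq[k], nodes_seq[k + 1]))
            tri_segs.append((s1, s2))

    triples = np.asarray(triples, dtype=np.int32).reshape(-1, 3)
    tri_segs = np.asarray(tri_segs, dtype=np.int32).reshape(-1, 2)
    tri_th0 = _angles(positions, triples)
    tri_L0 = 0.5 * (seg_L0[tri_segs[:, 0]] + seg_L0[tri_segs[:, 1]])

    # crosslink bookkeeping (CSR of incident crosslink-segment ids)
    xl_nodes = np.arange(n_xl, dtype=np.int32)
    incident_all = [[] for _ in range(n_xl)]
    incident_linked = [[] for _ in range(n_xl)]
    for e, (u, v) in enumerate(edges):
        incident_all[u].append(e)
        incident_all[v].append(e)
        if edge_xl_seg[e, 0] >= 0:
            incident_linked[u].append(int(edge_xl_seg[e, 0]))
        if edge_xl_seg[e, 1] >= 0:
            incident_linked[v].append(int(edge_xl_seg[e, 1]))
    n_ifs = np.array([len(x) for x in incident_all], dtype=np.int32)
    n_f0 = np.array([len(x) for x in incident_linked], dtype=np.int32)
    xl_seg_ptr = np.concatenate([[0], np.cumsum(n_f0)]).astype(np.int64)
    xl_seg_ids = np.array(
        [s for lst in incident_linked for s in lst], dtype=np.int32
    )

    n_nodes = positions.shape[0]
    ligand_capacity = np.where(node_type == NODE_FIBER, params.ligand_capacity, 0)

    return FiberNetwork(
        positions=positions,
        node_type=node_type,
        segments=segments,
        seg_L0=seg_L0,
        seg_kind=seg_kind,
        seg_chain=seg_chain,
        seg_active=np.ones(len(segments), dtype=bool),
        chains=chains,
        triples=triples,
        tri_th0=tri_th0,
        tri_L0=tri_L0,
        tri_segs=tri_segs,
        xl_nodes=xl_nodes,
        xl_seg_ptr=xl_seg_ptr,
        xl_seg_ids=xl_seg_ids,
        n_ifs=n_ifs,
        n_f0=n_f0,
        n_uf=np.zeros(n_xl, dtype=np.int32),
        ligand_capacity=ligand_capacity.astype(np.int64),
        ligand_bound=np.zeros(n_nodes, dtype=np.int64),
        ecm_conc=np.full(n_nodes, params.ecm_conc0_m, dtype=np.float64),
        ecm_conc0=params.ecm_conc0_m,
        domain_um=params.domain_um,
        params=params,
    )


def _edge_segment_ids(edges, edge_xl_seg, edge_first_fseg, n_div):
    """Ordered segment ids along each edge (u → v); -1 for an absent
    (never-formed) crosslink segment."""
    out = []
    for e in range(len(edges)):
        segs = [int(edge_xl_seg[e, 0])]
        segs += [int(edge_first_fseg[e] + k) for k in range(n_div)]
        segs += [int(edge_xl_seg[e, 1])]
        out.append(segs)
    return out


def _join_coaxial(pts, edges, elen, crosslinked, angle_deg, rng):
    """Pair edges into extended fibers through shared crosslink nodes.

    Convention: with d_in the unit direction of travel entering a crosslink
    node and d_out the direction leaving it, the chain continues when the
    bend angle between them is below ``angle_deg`` (they are closer to
    collinear than to folded).  Equivalently the angle between the two
    outward-pointing segment directions exceeds 180° − angle_deg.
    """
    cos_thresh = np.cos(np.deg2rad(angle_deg))
    n_xl = pts.shape[0]
    incident: list[list[int]] = [[] for _ in range(n_xl)]
    for e, (u, v) in enumerate(edges):
        incident[u].append(e)
        incident[v].append(e)

    # partner[e] = (edge at u end or -1, edge at v end or -1)
    partner = {e: [-1, -1] for e in range(len(edges))}

    for node in range(n_xl):
        cand = []
        for ii, e1 in enumerate(incident[node]):
            end1 = 0 if edges[e1][0] == node else 1
            if not crosslinked[e1, end1]:
                continue  # a free end cannot carry the chain through the node
            d1 = pts[edges[e1][1]] - pts[edges[e1][0]]
            d1 = d1 / np.linalg.norm(d1)
            if end1 == 1:
                d1 = -d1  # point away from the node
            for e2 in incident[node][ii + 1:]:
                end2 = 0 if edges[e2][0] == node else 1
                if not crosslinked[e2, end2]:
                    continue
                d2 = pts[edges[e2][1]] - pts[edges[e2][0]]
                d2 = d2 / np.linalg.norm(d2)
                if end2 == 1:
                    d2 = -d2
                # continuation: travel in along e1 (-d1) then out along d2
                c = float(np.dot(-d1, d2))
                if c > cos_thresh:
                    cand.append((c, e1, end1, e2, end2))
        cand.sort(key=lambda t: (-t[0], t[1], t[3]))
        used = set()
        for c, e1, end1, e2, end2 in cand:
            if (e1, end1) in used or (e2, end2) in used:
                continue
            used.add((e1, end1))
            used.add((e2, end2))
            partner[e1][end1] = e2
            partner[e2][end2] = e1

    # walk chains
    visited = np.zeros(len(edges), dtype=bool)
    chains = []
    for e0 in range(len(edges)):
        if visited[e0]:
            continue
        # rewind to a chain terminus (or detect a loop)
        e, end = e0, 0
        steps = 0
        while partner[e][end] >= 0 and steps <= len(edges):
            nxt = partner[e][end]
            node = edges[e][end]
            end = 1 if edges[nxt][0] == node else 0  # continue past nxt's far end
            e = nxt
            steps += 1
            if e == e0:
                break  # loop
        # walk forward from terminus e, leaving through its other end
        chain = []
        cur, cur_end = e, 1 - end
        while True:
            if visited[cur]:
                break
            visited[cur] = True
            forward = cur_end == 1  # traversal u→v?
            chain.append((int(cur), bool(forward)))
            nxt = partner[cur][cur_end]
            if nxt < 0 or visited[nxt]:
                break
            node = edges[cur][cur_end]
            cur_end = 1 if edges[nxt][0] == node else 0
            cur = nxt
        if chain:
            chains.append(chain)
    return chains


def _angles(positions, triples):
    if len(triples) == 0:
        return np.zeros(0)
    u = positions[triples[:, 1]] - positions[triples[:, 0]]
    v = positions[triples[:, 2]] - positions[triples[:, 1]]
    un = u / np.linalg.norm(u, axis=1, keepdims=True)
    vn = v / np.linalg.norm(v, axis=1, keepdims=True)
    c = np.clip((un * vn).sum(axis=1), -1.0, 1.0)
    return np.arccos(c)


# ---------------------------------------------------------------------------
# degradation


def round_half_up(x: np.ndarray | float) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)


def apply_crosslink_degradation(
    network: FiberNetwork, rng: np.random.Generator, inplace: bool = True
) -> FiberNetwork:
    """Detach crosslink couplings according to local ECM integrity.

    At crosslink node k the target detached count is
    ``N_uf = round_half_up((1 − I_k) · N_0f)``; newly detached couplings are
    drawn uniformly among the still-attached ones.  Monotone: ``N_uf`` never
    decreases and detached couplings never re-form.
    """
    net = network if inplace else network.copy()
    integ = net.ecm_conc[net.xl_nodes] / net.ecm_conc0
    if np.any((integ < -1e-9) | (integ > 1 + 1e-9)):
        raise ValueError("ECM integrity outside [0, 1]")
    integ = np.clip(integ, 0.0, 1.0)
    target = round_half_up((1.0 - integ) * net.n_f0)
    need = target - net.n_uf
    hot = np.where(need > 0)[0]
    for k in hot:
        lo, hi = net.xl_seg_ptr[k], net.xl_seg_ptr[k + 1]
        seg_ids = net.xl_seg_ids[lo:hi]
        alive = seg_ids[net.seg_active[seg_ids]]
        take = min(int(need[k]), alive.size)
        if take > 0:
            chosen = rng.choice(alive, size=take, replace=False)
            net.seg_active[chosen] = False
        net.n_uf[k] = net.n_f0[k] - int(net.seg_active[seg_ids].sum())
    return net


__all__ = [
    "NetworkParams",
    "FiberNetwork",
    "NetworkSizingError",
    "build_network",
    "apply_crosslink_degradation",
    "round_half_up",
    "NODE_CROSSLINK",
    "NODE_FIBER",
    "SEG_FIBER",
    "SEG_CROSSLINK",
]
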