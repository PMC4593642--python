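"""Fixtures, serialization and result output shared by all modules.

Networks serialize to a documented JSON container (text, portable); fibers
and concentration fields export to legacy-ASCII VTK for visualization.  The
``write_outputs`` bundle writer emits CSV/JSON artifacts plus a manifest
carrying the configuration hash, seed and package version so reruns are
auditable.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import MotorBindingConfig, SimConfig
from .network import (
    NODE_FIBER,
    SEG_FIBER,
    FiberNetwork,
    NetworkParams,
    build_network,
)

# ---------------------------------------------------------------------------
# network serialization


def save_network_json(network: FiberNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network.to_dict(), fh)


def load_network_json(path) -> FiberNetwork:
    with open(path) as fh:
        return FiberNetwork.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# VTK (legacy ASCII) export


def write_vtk_polylines(network: FiberNetwork, path) -> None:
    """Fibers as polylines (one line per active segment) in legacy VTK."""
    pos = network.positions
    act = np.where(network.seg_active)[0]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfilosim fibers\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pos)} float\n")
        for p in pos:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"LINES {len(act)} {3 * len(act)}\n")
        for s in act:
            i, j = network.segments[s]
            fh.write(f"2 {i} {j}\n")
        fh.write(f"POINT_DATA {len(pos)}\n")
        fh.write("SCALARS integrity float 1\nLOOKUP_TABLE default\n")
        for v in network.integrity():
            fh.write(f"{v:.6g}\n")


def write_vtk_cell(cell, path) -> None:
    """The three membrane shells (cell, transduce, nucleus) as one legacy-VTK
    polydata; a per-point shell id distinguishes the layers."""
    pts = np.vstack([cell.x_c, cell.x_t, cell.x_n])
    n = cell.n_nodes
    tris = np.vstack([cell.triangles + off for off in (0, n, 2 * n)])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfilosim cell\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"POLYGONS {len(tris)} {4 * len(tris)}\n")
        for a, b, c in tris:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"POINT_DATA {len(pts)}\n")
        fh.write("SCALARS shell int 1\nLOOKUP_TABLE default\n")
        for shell in (0, 1, 2):
            fh.write(f"{shell}\n" * n)


def write_vtk_image(fields, species: str, path) -> None:
    """One concentration array as legacy VTK structured points."""
    arr = fields.data[species]
    nx, ny, nz = arr.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfilosim field\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        o = fields.origin
        fh.write(f"ORIGIN {o[0]} {o[1]} {o[2]}\n")
        fh.write(f"SPACING {fields.h} {fields.h} {fields.h}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {species} float 1\nLOOKUP_TABLE default\n")
        for v in arr.ravel(order="F"):
            fh.write(f"{v:.6g}\n")


# ---------------------------------------------------------------------------
# result bundles


def write_outputs(bundle: dict, out_dir, config: SimConfig | None = None) -> dict:
    """Write a run bundle (CSV/JSON) and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for i, rep in enumerate(bundle.get("replicates", [])):
        if rep.get("failed"):
            continue
        log = rep.get("log")
        if log:
            df = pd.DataFrame(
                log, columns=["t", "filo", "state", "length_um", "bonds",
                              "tension_pn", "tip_x", "tip_y", "tip_z"]
            )
            name = f"events_rep{i}.csv"
            df.to_csv(out / name, index=False, float_format="%.6g")
            written.append(name)
    summary = {k: v for k, v in bundle.items() if k in ("summary", "seeds")}
    reps_meta = [
        {k: v for k, v in rep.items() if k not in ("log",)}
        for rep in bundle.get("replicates", [])
    ]
    summary["replicates"] = reps_meta
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    written.append("summary.json")
    manifest = {
        "version": __version__,
        "files": written,
        "config_hash": config.config_hash() if config is not None else None,
        "seed": config.seed if config is not None else None,
    }
    manifest["content_hash"] = hashlib.sha256(
        json.dumps(summary, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# fixtures


def make_single_segment_network(L0: float = 1.0, kappa_axis=(1.0, 0.0, 0.0),
                                ligand_capacity: int = 300) -> FiberNetwork:
    """Two fiber nodes joined by one segment at rest (minimal test network)."""
    axis = np.asarray(kappa_axis, dtype=float)
    axis /= np.linalg.norm(axis)
    positions = np.vstack([np.zeros(3), L0 * axis])
    return network_from_arrays(
        positions,
        segments=np.array([[0, 1]], dtype=np.int32),
        chains=[np.array([0, 1], dtype=np.int32)],
        triples=np.zeros((0, 3), dtype=np.int32),
        ligand_capacity=ligand_capacity,
        domain=(L0, L0, L0),
    )


def make_single_fiber_network(center=(3.0, 0.0, 0.0), axis=(0.0, 1.0, 0.0),
                              length: float = 3.0, n_seg: int = 6,
                              ligand_capacity: int = 300) -> FiberNetwork:
    """One straight multi-segment fiber (the single-filopodium scene)."""
    center = np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    ts = np.linspace(-length / 2, length / 2, n_seg + 1)
    positions = center[None, :] + ts[:, None] * axis[None, :]
    segments = np.column_stack(
        [np.arange(n_seg), np.arange(1, n_seg + 1)]).astype(np.int32)
    triples = np.column_stack(
        [np.arange(n_seg - 1), np.arange(1, n_seg), np.arange(2, n_seg + 1)]
    ).astype(np.int32)
    return network_from_arrays(
        positions, segments, [np.arange(n_seg + 1, dtype=np.int32)], triples,
        ligand_capacity, domain=(length, length, length),
    )


def make_random_chain_network(n_chains: int = 3, n_nodes: int = 6,
                              seed: int = 0, box: float = 2.0) -> FiberNetwork:
    """Small random bent-chain network for gradient-oracle tests."""
    rng = np.random.default_rng(seed)
    positions, segments, chains, triples = [], [], [], []
    offset = 0
    for _ in range(n_chains):
        start = rng.uniform(0, box, 3)
        steps = rng.normal(0, 0.25, (n_nodes - 1, 3))
        pts = np.vstack([start, start + np.cumsum(steps, axis=0)])
        positions.append(pts)
        ids = offset + np.arange(n_nodes)
        segments.append(np.column_stack([ids[:-1], ids[1:]]))
        chains.append(ids.astype(np.int32))
        triples.append(np.column_stack([ids[:-2], ids[1:-1], ids[2:]]))
        offset += n_nodes
    return network_from_arrays(
        np.concatenate(positions), np.concatenate(segments).astype(np.int32),
        chains, np.concatenate(triples).astype(np.int32), 300,
        domain=(box, box, box),
    )


def network_from_arrays(positions, segments, chains, triples,
                         ligand_capacity, domain) -> FiberNetwork:
    n = len(positions)
    seg_L0 = np.linalg.norm(
        positions[segments[:, 1]] - positions[segments[:, 0]], axis=1)
    if len(triples):
        u = positions[triples[:, 1]] - positions[triples[:, 0]]
        v = positions[triples[:, 2]] - positions[triples[:, 1]]
        un = u / np.linalg.norm(u, axis=1, keepdims=True)
        vn = v / np.linalg.norm(v, axis=1, keepdims=True)
        th0 = np.arccos(np.clip((un * vn).sum(axis=1), -1, 1))
        tri_segs = np.column_stack(
            [np.arange(len(triples)), np.arange(len(triples))]).astype(np.int32)
        # map bend triples onto their flanking segments by lookup
        seg_lookup = {(int(a), int(b)): i for i, (a, b) in enumerate(segments)}
        ts = []
        for a, b, c in triples:
            s1 = seg_lookup.get((int(a), int(b)), seg_lookup.get((int(b), int(a))))
            s2 = seg_lookup.get((int(b), int(c)), seg_lookup.get((int(c), int(b))))
            ts.append((s1, s2))
        tri_segs = np.asarray(ts, dtype=np.int32)
        tri_L0 = 0.5 * (seg_L0[tri_segs[:, 0]] + seg_L0[tri_segs[:, 1]])
    else:
        th0 = np.zeros(0)
        tri_L0 = np.zeros(0)
        tri_segs = np.zeros((0, 2), dtype=np.int32)
    return FiberNetwork(
        positions=np.ascontiguousarray(positions, dtype=np.float64),
        node_type=np.full(n, NODE_FIBER, dtype=np.uint8),
        segments=segments,
        seg_L0=seg_L0,
        seg_kind=np.full(len(segments), SEG_FIBER, dtype=np.uint8),
        seg_chain=np.zeros(len(segments), dtype=np.int32),
        seg_active=np.ones(len(segments), dtype=bool),
        chains=[np.asarray(c, dtype=np.int32) for c in chains],
        triples=np.asarray(triples, dtype=np.int32).reshape(-1, 3),
        tri_th0=th0,
        tri_L0=tri_L0,
        tri_segs=tri_segs,
        xl_nodes=np.zeros(0, dtype=np.int32),
        xl_seg_ptr=np.zeros(1, dtype=np.int64),
        xl_seg_ids=np.zeros(0, dtype=np.int32),
        n_ifs=np.zeros(0, dtype=np.int32),
        n_f0=np.zeros(0, dtype=np.int32),
        n_uf=np.zeros(0, dtype=np.int32),
        ligand_capacity=np.full(n, ligand_capacity, dtype=np.int64),
        ligand_bound=np.zeros(n, dtype=np.int64),
        ecm_conc=np.full(n, 10e-6),
        ecm_conc0=10e-6,
        domain_um=tuple(domain),
    )


def make_fixture(name: str, seed: int = 1234):
    """Canned deterministic scenes for tests and examples."""
    if name == "single-segment":
        return make_single_segment_network()
    if name == "single-fiber":
        return make_single_fiber_network()
    if name == "one-filopodium-one-fiber":
        from .filopodium import make_filopodium
        net = make_single_fiber_network(center=(2.05, 0.0, 0.0))
        filo = make_filopodium(np.zeros(3), (1.0, 0.0, 0.0),
                               MotorBindingConfig(), length=2.0)
        return net, filo   # tip 50 nm from the fiber axis
    if name == "lattice-5um":
        params = NetworkParams(pore_size_um=1.0, fiber_diameter_nm=34.0,
                               n_div=2, domain_um=(5.0, 5.0, 5.0), seed=seed)
        return build_network(params)
    if name == "random-net":
        return make_random_chain_network(seed=seed)
    raise KeyError(f"unknown fixture {name!r}")


__all__ = [
    "save_network_json",
    "load_network_json",
    "write_vtk_polylines",
    "write_vtk_cell",
    "write_vtk_image",
    "write_outputs",
    "make_fixture",
    "make_single_segment_network",
    "make_single_fiber_network",
    "make_random_chain_network",
    "network_from_arrays",
]
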