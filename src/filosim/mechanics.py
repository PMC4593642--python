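"""Elastic energies and nodal forces of the fiber network, and the in-silico
uniaxial stretch test with bulk-modulus fitting.

A fiber of radius r and Young's modulus E_f carries a stretching modulus
κ_s = E_f·π r² (pN) and a bending modulus κ_b = E_f·π r⁴/4 (pN·μm²).  The
elastic energy of a chain is

    H = κ_s/2 Σ_j (L_j − L0_j)²/L0_j  +  κ_b/2 Σ_j (θ_j − θ0_j)²/L0_j

summed over coaxial neighbours only; nodal forces are the exact negative
gradient (virtual work), evaluated by the numba kernels and cross-checked
against central differences in the test suite.

The stretch test displaces the two opposing boundary faces at a nominal
constant speed and relaxes the interior quasi-statically (FIRE minimizer)
between strain increments; stress is the summed axial boundary reaction
divided by the undeformed cross-section, so 1 pN/μm² ≡ 1 Pa.  The bulk
modulus is the least-squares slope of stress vs strain over [0.2, 0.7].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .config import MaterialConfig
from .network import FiberNetwork


@dataclass
class FiberMaterial:
    """Material constants of a single fiber, in package units."""

    youngs_modulus: float          # E_f, Pa (= pN/μm²)
    radius_um: float               # r_f
    drag: float = 1000.0           # C_e, pN·s/μm (0.001 N·s/m)
    bend_modulus_override: float | None = None

    @classmethod
    def from_diameter(cls, diameter_nm: float, youngs_modulus_pa: float = 1e6,
                      drag_n_s_per_m: float = 0.001,
                      bend_modulus_override: float | None = None) -> "FiberMaterial":
        return cls(
            youngs_modulus=youngs_modulus_pa,
            radius_um=0.5 * diameter_nm * 1e-3,
            drag=drag_n_s_per_m * 1e6,
            bend_modulus_override=bend_modulus_override,
        )

    @classmethod
    def from_config(cls, cfg: MaterialConfig) -> "FiberMaterial":
        return cls.from_diameter(
            cfg.fiber_diameter_nm, cfg.youngs_modulus_pa, cfg.drag_n_s_per_m,
            cfg.bend_modulus_override,
        )

    @property
    def area_um2(self) -> float:
        """A_f = π r², μm²."""
        return math.pi * self.radius_um**2

    @property
    def second_moment_um4(self) -> float:
        """I_f = π r⁴/4, μm⁴."""
        return math.pi * self.radius_um**4 / 4.0

    @property
    def stretch_modulus_pn(self) -> float:
        """κ_s = E_f·A_f, pN."""
        return self.youngs_modulus * self.area_um2

    @property
    def bend_modulus_pn_um2(self) -> float:
        """κ_b = E_f·I_f, pN·μm² (overridable)."""
        if self.bend_modulus_override is not None:
            return self.bend_modulus_override
        return self.youngs_modulus * self.second_moment_um4


def _coefficients(network: FiberNetwork, material: FiberMaterial):
    """Per-segment κ_s/L0 and per-triple κ_b/L0 arrays for the kernels."""
    if np.any(network.seg_L0 <= 0):
        raise ValueError("invalid network: zero rest length segment")
    klin = material.stretch_modulus_pn / network.seg_L0
    kb = material.bend_modulus_pn_um2 / network.tri_L0 if len(network.tri_L0) else network.tri_L0
    return klin, kb


def elastic_energy(network: FiberNetwork, material: FiberMaterial,
                   positions: np.ndarray | None = None) -> float:
    """Total elastic energy (pN·μm) of the network at the given positions."""
    pos = np.ascontiguousarray(positions if positions is not None else network.positions)
    _, kb = _coefficients(network, material)
    ks = np.full(network.n_segments, material.stretch_modulus_pn)
    return float(_kernels.network_energy(
        pos, network.segments[:, 0], network.segments[:, 1], ks,
        network.seg_L0, network.seg_active,
        network.triples[:, 0], network.triples[:, 1], network.triples[:, 2],
        kb, network.tri_th0, network.tri_active(),
    ))


def elastic_forces(network: FiberNetwork, material: FiberMaterial,
                   positions: np.ndarray | None = None) -> np.ndarray:
    """Per-node force −∂H/∂x (pN); sums to zero over an isolated network."""
    pos = np.ascontiguousarray(positions if positions is not None else network.positions)
    klin, kb = _coefficients(network, material)
    F = np.zeros_like(pos)
    _kernels.network_forces(
        pos, F, network.segments[:, 0], network.segments[:, 1], klin,
        network.seg_L0, network.seg_active,
        network.triples[:, 0], network.triples[:, 1], network.triples[:, 2],
        kb, network.tri_th0, network.tri_active(),
    )
    return F


@dataclass
class StressStrainCurve:
    strains: np.ndarray            # dimensionless, strictly increasing from 0
    stresses: np.ndarray           # Pa
    stretch_speed_nm_s: float
    fit_window: tuple[float, float] = (0.2, 0.7)
    flagged: np.ndarray | None = None   # non-equilibrated samples
    fitted_modulus: float | None = field(default=None)

    def fit(self) -> float:
        self.fitted_modulus = fit_bulk_modulus(self)
        return self.fitted_modulus


class InsufficientDataError(ValueError):
    pass


def fit_bulk_modulus(curve: StressStrainCurve,
                     window: tuple[float, float] | None = None) -> float:
    """Least-squares slope (Pa) of stress vs strain inside the fit window."""
    lo, hi = window if window is not None else curve.fit_window
    mask = (curve.strains >= lo - 1e-12) & (curve.strains <= hi + 1e-12)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 samples in the strain window [{lo}, {hi}], got {int(mask.sum())}"
        )
    slope, _ = np.polyfit(curve.strains[mask], curve.stresses[mask], 1)
    return float(slope)


def run_stretch_test(network: FiberNetwork, material: FiberMaterial,
                     speed_nm_s: float = 0.5, max_strain: float = 0.75,
                     strain_step: float = 0.05, axis: int = 0,
                     residual_tol_pn: float = 0.5,
                     max_fire_steps: int = 20000) -> StressStrainCurve:
    """Uniaxial stretch test: displace both boundary faces symmetrically and
    record stress per strain increment after quasi-static relaxation.

    The nominal stretch speed is recorded as metadata; the protocol is
    quasi-static (the lab speeds of 0.25–1 nm/s are far below the network
    relaxation scale, so the recorded curve is the rate-independent limit).
    Samples whose residual force exceeds ``residual_tol_pn`` are flagged.
    """
    net = network.copy()
    pos = np.ascontiguousarray(net.positions)
    pos0 = pos.copy()                      # undeformed reference for the grips
    lo, hi = net.boundary_sets(axis=axis)
    grip = np.zeros(net.n_nodes, dtype=bool)
    grip[lo] = True
    grip[hi] = True
    free = ~grip
    klin, kb = _coefficients(net, material)
    L0_dom = pos[hi][:, axis].mean() - pos[lo][:, axis].mean()
    extents = [net.domain_um[d] for d in range(3) if d != axis]
    area = extents[0] * extents[1]

    # FIRE step capped by the stiffest segment (unit pseudo-mass)
    k_max = klin.max()
    dt_cap = 0.5 / math.sqrt(k_max)

    strains = [0.0]
    stresses = [0.0]
    flags = [False]
    n_steps = max(1, int(round(max_strain / strain_step)))
    for step in range(1, n_steps + 1):
        eps = step * max_strain / n_steps
        delta = eps * L0_dom
        # move both grips symmetrically to the configuration for this strain
        pos[lo, axis] = pos0[lo, axis] - 0.5 * delta
        pos[hi, axis] = pos0[hi, axis] + 0.5 * delta
        res, _ = _kernels.fire_relax(
            pos, free, residual_tol_pn, 0.1 * dt_cap, dt_cap, max_fire_steps,
            net.segments[:, 0], net.segments[:, 1], klin, net.seg_L0,
            net.seg_active,
            net.triples[:, 0], net.triples[:, 1], net.triples[:, 2],
            kb, net.tri_th0, net.tri_active(),
        )
        F = np.zeros_like(pos)
        _kernels.network_forces(
            pos, F, net.segments[:, 0], net.segments[:, 1], klin, net.seg_L0,
            net.seg_active,
            net.triples[:, 0], net.triples[:, 1], net.triples[:, 2],
            kb, net.tri_th0, net.tri_active(),
        )
        # reaction applied by the grip = −(elastic force on grip nodes)
        stress = -F[hi][:, axis].sum() / area
        strains.append(eps)
        stresses.append(float(stress))
        flags.append(bool(res > residual_tol_pn))

    return StressStrainCurve(
        strains=np.asarray(strains),
        stresses=np.asarray(stresses),
        stretch_speed_nm_s=speed_nm_s,
        flagged=np.asarray(flags),
    )


__all__ = [
    "FiberMaterial",
    "StressStrainCurve",
    "InsufficientDataError",
    "elastic_energy",
    "elastic_forces",
    "fit_bulk_modulus",
    "run_stretch_test",
]
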