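"""Pre-registered scaled-down study conditions.

These functions fix the problem sizes and integrator settings used for the
package's headline computational experiments, so tests, examples and scripts
all run the same conditions:

* rheology: in-silico uniaxial stretch tests on 10 μm pore-1.0 networks,
  sweeping fiber diameter (28/34/41 nm) and single-fiber modulus
  (0.25/1 MPa), modulus fitted over strain 0.2–0.7;
* invasion: one cell (radius 2 μm, 549 membrane nodes) invading a
  15×5×5 μm fiber network for 10 simulated minutes, N = 5 seeds per pore
  preset (0.5/1.0/1.5 μm with fiber diameters 28/34/41 nm);
* proteolysis contrast: the pore-0.5 invasion conditions re-run for 5
  simulated minutes with matrix degradation enabled vs disabled (an
  MT1-MMP-deficient cell), identical seeds.

The invasion integrator rides a coarser step ceiling (dt ≤ 0.15 s, RMS
local-error tolerance 1e-3 μm) than the engine default; the linearly
implicit per-node damping keeps the stiff bond clusters stable there, and
the observables are minute-scale trajectory statistics.
"""

from __future__ import annotations

import numpy as np

from .config import PRESETS, SimConfig
from .engine import run_replicate, run_simulation
from .mechanics import FiberMaterial, fit_bulk_modulus, run_stretch_test
from .network import NetworkParams, build_network

INVASION_DOMAIN_UM = (15.0, 5.0, 5.0)
INVASION_TIME_S = 600.0
DEGRADATION_TIME_S = 300.0
RHEOLOGY_DOMAIN_UM = (10.0, 10.0, 10.0)
DIAMETER_SWEEP_NM = (28.0, 34.0, 41.0)
MODULUS_SWEEP_PA = (0.25e6, 1.0e6)


def invasion_config(preset: str, seed: int, replicates: int = 5) -> SimConfig:
    cfg = SimConfig(seed=seed, preset=preset, replicates=replicates)
    cfg.network.domain_um = INVASION_DOMAIN_UM
    cfg.engine.ode_tolerance = 1e-3
    cfg.engine.dt_max = 0.15
    cfg.engine.event_dt = 0.3
    cfg.engine.total_time_s = INVASION_TIME_S
    return cfg


def run_invasion_study(seed: int, presets=None, replicates: int = 5,
                       total_time: float | None = None) -> dict:
    """Invasion replicates for every pore preset; returns per-preset bundles
    with mean ± SEM tip/root speeds (μm/s)."""
    presets = sorted(PRESETS) if presets is None else list(presets)
    out = {}
    for name in presets:
        cfg = invasion_config(name, seed, replicates)
        out[name] = run_simulation(cfg, total_time=total_time)
    return out


def run_degradation_comparison(seed: int, replicates: int = 5,
                               total_time: float = DEGRADATION_TIME_S) -> dict:
    """Pore-0.5 invasion with vs without ECM degradation, same seeds.

    Returns per-arm mean cell-centroid advances along the invasion axis.
    """
    cfg = invasion_config("pore0.5", seed, replicates)
    seeds = cfg.rng_streams().replicate_seeds(replicates)
    out = {"seeds": seeds}
    for label, enabled in (("degradation_on", True), ("degradation_off", False)):
        cfg_arm = invasion_config("pore0.5", seed, replicates)
        cfg_arm.rd.degradation_enabled = enabled
        advances = []
        roots = []
        for s in seeds:
            rep = run_replicate(cfg_arm, s, total_time=total_time)
            advances.append(rep["centroid_advance_x"])
            roots.append(rep["mean_root"])
        out[label] = {
            "advances": advances,
            "mean_advance": float(np.mean(advances)),
            "root_speeds": roots,
        }
    return out


def run_rheology_study(seed: int, pore_size_um: float = 1.0,
                       strain_step: float = 0.05) -> dict:
    """Stretch-test sweeps: fitted bulk modulus vs fiber diameter and vs
    single-fiber Young's modulus, one fixed network geometry per sweep."""
    params = NetworkParams(
        pore_size_um=pore_size_um, fiber_diameter_nm=34.0, n_div=2,
        domain_um=RHEOLOGY_DOMAIN_UM, seed=seed,
    )
    network = build_network(params)
    moduli_by_diameter = {}
    for d in DIAMETER_SWEEP_NM:
        mat = FiberMaterial.from_diameter(d, 1.0e6)
        curve = run_stretch_test(network, mat, strain_step=strain_step)
        moduli_by_diameter[d] = fit_bulk_modulus(curve)
    moduli_by_ef = {}
    for ef in MODULUS_SWEEP_PA:
        mat = FiberMaterial.from_diameter(34.0, ef)
        curve = run_stretch_test(network, mat, strain_step=strain_step)
        moduli_by_ef[ef] = fit_bulk_modulus(curve)
    return {
        "moduli_by_diameter_pa": moduli_by_diameter,
        "moduli_by_ef_pa": moduli_by_ef,
    }


__all__ = [
    "invasion_config",
    "run_invasion_study",
    "run_degradation_comparison",
    "run_rheology_study",
    "INVASION_DOMAIN_UM",
    "INVASION_TIME_S",
    "DEGRADATION_TIME_S",
]
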