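"""Simulation configuration: physical parameters, presets, and RNG streams.

Internal unit system (used consistently across the package):

========  =========================
quantity  unit
========  =========================
length    μm
time      s
force     pN
energy    pN·μm  (= 1e-18 J)
stiffness pN/μm  (1 N/m = 1e6 pN/μm)
drag      pN·s/μm (1 N·s/m = 1e6 pN·s/μm)
pressure  Pa     (= pN/μm²)
conc.     M
========  =========================

Every default physical constant is collected here so the rest of the code
never hard-codes a number.  ``SimConfig`` groups them into the blocks the
individual modules consume, supports strict YAML round-tripping, and derives
named, reproducible RNG substreams from a single root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from typing import Any

import numpy as np
import yaml

# Boltzmann constant times T = 310 K, in pN·μm (1 k_B·T = 4.28 pN·nm at 310 K).
BOLTZMANN_PN_UM_PER_K = 1.380649e-23 * 1e18  # pN·μm per K
DEFAULT_TEMPERATURE_K = 310.0


def thermal_energy(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """k_B·T in pN·μm."""
    return BOLTZMANN_PN_UM_PER_K * temperature_k


@dataclass
class MaterialConfig:
    """Single-fiber material constants (collagen)."""

    youngs_modulus_pa: float = 1.0e6     # E_f, 1 MPa
    fiber_diameter_nm: float = 34.0
    drag_n_s_per_m: float = 0.001        # C_e
    #: optional override for the bending modulus (pN·μm²); None → E_f·π r⁴/4
    bend_modulus_override: float | None = None


@dataclass
class NetworkConfig:
    """Procedural fiber-network generation."""

    pore_size_um: float = 1.0
    n_div: int | None = None             # None → preset rule round(pore/0.5)
    crosslink_segment_um: float = 0.03   # 30 nm crosslink segments
    p_f: float = 0.7                     # initial crosslinking ratio
    ligand_capacity: int = 300           # A_L·C_L molecules per fiber node
    domain_um: tuple[float, float, float] = (10.0, 10.0, 10.0)
    jitter: float = 0.12                 # lattice jitter as fraction of pore
    edge_cutoff_factor: float = 1.45     # prune Delaunay edges > factor×pore
    ecm_conc0_m: float = 10e-6           # C_ECM0, 10 μM
    continuation_angle_deg: float = 60.0 # coaxial-joining bend threshold


@dataclass
class MotorBindingConfig:
    """Filopodial motor, bond-kinetic and state-machine constants."""

    v_m0_um_s: float = 0.010             # unloaded myosin sliding rate, 10 nm/s
    f_stall_pn: float = 1000.0           # 1 nN
    c_m: float = 0.1
    e_am_pa: float = 230e3               # AM Young's modulus, 230 kPa
    a_am_um2: float = 7.07e-2            # AM cross-sectional area
    f_p_max_pn: float = 2000.0           # protrusion force, 2 nN
    k_f: float = 1.0                     # forward rate, molecule⁻¹ s⁻¹
    k_off0: float = 1.0                  # unstressed dissociation rate, s⁻¹
    x_b_um: float = 0.02e-3              # Bell distance, 0.02 nm
    temperature_k: float = DEFAULT_TEMPERATURE_K
    kappa_lr_pn_um: float = 1000.0       # bond spring, 1 pN/nm
    lambda_um: float = 0.03              # unstressed bond length, 30 nm
    contact_range_um: float = 0.1        # FC formation gate, 100 nm
    contractile_threshold_pn_per_um: float = 3.0  # lower end of 3–4 nN/μm
    filopodium_diameter_um: float = 0.3
    n_am: int = 8                        # AM compartments per filopodium
    n_receptors: int = 300               # integrins available at the tip node
    v_poly_um_s: float = 0.05            # polymerization elongation rate
    l_max_um: float = 4.5
    l_min_um: float = 2.0
    outgrow_budget_s: float = 60.0
    tugging_budget_s: float = 60.0
    contractile_budget_s: float = 300.0
    polarity_angle_deg: float = 45.0
    max_filopodia: int = 4
    nucleation_rate_per_s: float = 0.1
    drag_n_s_per_m: float = 0.001        # C_f
    am_rest_floor_um: float = 0.05
    fc_detach_distance_um: float = 0.5   # geometric release of a stretched FC

    @property
    def contractile_threshold_pn(self) -> float:
        return self.contractile_threshold_pn_per_um * self.filopodium_diameter_um * 1e3

    @property
    def kt_pn_um(self) -> float:
        return thermal_energy(self.temperature_k)


@dataclass
class CellConfig:
    """Triple-membrane cell body."""

    n_membrane_nodes: int = 549
    radius_um: float = 2.0
    transduce_radius_frac: float = 0.9
    nucleus_radius_frac: float = 0.35
    kappa_memb_n_m: float = 5.0e-5       # membrane line elements
    kappa_cort_n_m: float = 8.0e-3       # cortex spring
    c_cort_n_s_m: float = 0.006          # cortex drag
    c_c_n_s_m: float = 0.001
    c_t_n_s_m: float = 0.001
    c_n_n_s_m: float = 0.001
    lamellipodium_force_pn: float = 300.0
    leading_edge_angle_deg: float = 60.0
    fa_bond_cap: int = 100
    fa_koff0_scale: float = 0.2          # slower FA turnover than FCs
    fa_range_um: float = 0.1
    fa_detach_distance_um: float = 0.5
    sf_maturity_bonds: int = 30          # FA bonds needed to nucleate an SF
    volume_penalty_pn_um5: float = 50.0  # nucleus/membrane volume preservation
    polarization_ema: float = 0.05


@dataclass
class RDConfig:
    """Reaction–diffusion constants (Table of kinetic rates)."""

    grid_um: float = 1.0
    d_vegf_um2_s: float = 68.8
    d_mmp2_um2_s: float = 68.8
    d_timp2_um2_s: float = 1.29
    d_ligand_um2_s: float = 1.0e-3
    k_vegf_decay: float = 8.2e-6         # s⁻¹
    k_mmp2_decay: float = 0.0017
    k_ligand_decay: float = 1.0e-4
    k_mt1mmp_decay: float = 0.0          # printed term, value not published
    k_ecm_deg: float = 1.04e6            # M⁻¹ s⁻¹
    k_on_timp2_mmp2: float = 5e5
    k_on_complex_mt1mmp: float = 1.95e4
    k_on_timp2_mt1mmp: float = 2.74e6
    k_off_complex: float = 2e-4
    alpha_timp2: float = 1.0e-3          # M s⁻¹ secretion factor
    alpha_mt1mmp: float = 1.0e-1
    c_vegf_far_m: float = 1.3e-9         # fixed far-face VEGF (≈50 ng/ml)
    c_ligand0_m: float = 10e-6
    secretion_times_ligand: bool = True  # α·C_Ligand as printed vs constant α
    complex_consumed_on_activation: bool = True
    degradation_enabled: bool = True


@dataclass
class EngineConfig:
    """Integrator and orchestration settings."""

    ode_tolerance: float = 1e-4          # local error per step, μm
    dt_min: float = 1e-3
    dt_max: float = 1e-2
    event_dt: float = 0.05               # stochastic-event macro-step
    rd_interval: float = 0.5
    active_domain_radius_um: float = 15.0
    active_domain_refresh_s: float = 10.0
    neighbor_refresh_s: float = 0.5
    contact_stiffness_pn_um: float = 2.0e4
    #: effective membrane node radius added to the fiber radius for contacts;
    #: kept below the 100 nm adhesion gate so FAs can still form
    membrane_node_radius_um: float = 0.06
    #: filopodial nodes contact bare fiber cylinders (no added radius) so the
    #: contact shell never blocks the focal-complex formation gate
    filopodium_node_radius_um: float = 0.0
    snapshot_cadence_s: float = 1.0
    total_time_s: float = 600.0
    boundary_freeze_um: float = 0.3


#: pore-size presets binding pore size ↔ fiber diameter ↔ n_div
PRESETS: dict[str, dict[str, float | int]] = {
    "pore0.5": {"pore_size_um": 0.5, "fiber_diameter_nm": 28.0, "n_div": 1},
    "pore1.0": {"pore_size_um": 1.0, "fiber_diameter_nm": 34.0, "n_div": 2},
    "pore1.5": {"pore_size_um": 1.5, "fiber_diameter_nm": 41.0, "n_div": 3},
}


def default_n_div(pore_size_um: float) -> int:
    """Segments per fiber: 1/2/3 for the 0.5/1.0/1.5 μm presets."""
    return max(1, int(round(pore_size_um / 0.5)))


@dataclass
class SimConfig:
    """Root configuration: nested parameter groups plus run settings."""

    seed: int | None = None
    preset: str | None = None
    replicates: int = 5
    network: NetworkConfig = field(default_factory=NetworkConfig)
    material: MaterialConfig = field(default_factory=MaterialConfig)
    motor: MotorBindingConfig = field(default_factory=MotorBindingConfig)
    cell: CellConfig = field(default_factory=CellConfig)
    rd: RDConfig = field(default_factory=RDConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)

    def __post_init__(self) -> None:
        if self.preset is not None:
            self.apply_preset(self.preset)

    def apply_preset(self, name: str) -> None:
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        p = PRESETS[name]
        self.preset = name
        self.network.pore_size_um = float(p["pore_size_um"])
        self.network.n_div = int(p["n_div"])
        self.material.fiber_diameter_nm = float(p["fiber_diameter_nm"])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return _asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimConfig":
        return _from_dict(cls, dict(data))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- RNG ---------------------------------------------------------------

    def rng_streams(self) -> "RngStreams":
        if self.seed is None:
            raise ConfigError("a seed is required (determinism): set config.seed")
        return RngStreams(int(self.seed))


class ConfigError(ValueError):
    """Raised for unknown keys, bad units or missing required fields."""


_SUBSTREAMS = ("network", "binding", "rupture", "nucleation", "placement", "replicates")


class RngStreams:
    """Named, independent RNG substreams derived from one root seed."""

    def __init__(self, seed: int):
        self.seed = seed
        root = np.random.SeedSequence(seed)
        children = root.spawn(len(_SUBSTREAMS))
        self._streams = {
            name: np.random.Generator(np.random.PCG64(ss))
            for name, ss in zip(_SUBSTREAMS, children)
        }

    def __getattr__(self, name: str) -> np.random.Generator:
        try:
            return self._streams[name]
        except KeyError:  # pragma: no cover
            raise AttributeError(name) from None

    def replicate_seeds(self, n: int) -> list[int]:
        """Deterministic per-replicate integer seeds below 2**31."""
        return [int(s) for s in self._streams["replicates"].integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# strict (unknown-key-rejecting) dataclass <-> dict conversion


def _asdict(obj) -> Any:
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _from_dict(cls, data: dict[str, Any]):
    if not isinstance(data, dict):
        raise ConfigError(f"expected mapping for {cls.__name__}, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {cls.__name__}: {sorted(unknown)}; "
            f"known keys: {sorted(known)}"
        )
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        value = data[name]
        ftype = f.type if isinstance(f.type, type) else None
        if dataclasses.is_dataclass(_resolve_group_type(cls, name)):
            kwargs[name] = _from_dict(_resolve_group_type(cls, name), value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
        del ftype
    return cls(**kwargs)


_GROUP_TYPES = {
    "network": NetworkConfig,
    "material": MaterialConfig,
    "motor": MotorBindingConfig,
    "cell": CellConfig,
    "rd": RDConfig,
    "engine": EngineConfig,
}


def _resolve_group_type(cls, name: str):
    if cls is SimConfig:
        return _GROUP_TYPES.get(name)
    return None


__all__ = [
    "SimConfig",
    "NetworkConfig",
    "MaterialConfig",
    "MotorBindingConfig",
    "CellConfig",
    "RDConfig",
    "EngineConfig",
    "ConfigError",
    "RngStreams",
    "PRESETS",
    "default_n_div",
    "thermal_energy",
]
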