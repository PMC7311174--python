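"""Model parameters, presets, and configuration I/O.

All tunable quantities of the spindle model live here, grouped into blocks
that mirror the physical subsystems: simulation geometry, spindle-pole
bodies (SPBs), nuclear envelope, microtubules (MTs), the three
motor/crosslinker species, chromosomes/kinetochores, kinetochore-MT
attachment factors, error correction, and anaphase.

Field names carry the unit they are expressed in (``_um_min``, ``_pn_nm``,
...).  Internally the simulation engine works in pN / nm / s with
kBT = 4.114 pN nm; :func:`ModelParams.pack` performs the conversion once
and produces a flat ``float64`` vector consumed by the numba kernel, with
:data:`PARAM_INDEX` mapping names to slots.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

KBT_PN_NM = 4.114  # room-temperature thermal energy, pN nm

UM_MIN_TO_NM_S = 1000.0 / 60.0
PER_MIN_TO_PER_S = 1.0 / 60.0
UM2_S_TO_NM2_S = 1.0e6


class ConfigError(ValueError):
    """Raised for unknown keys, unit/type mismatches, or out-of-range values."""


@dataclass
class SimulationParams:
    """Global integration and geometry parameters."""

    time_step_s: float = 8.9e-6
    nucleus_radius_um: float = 1.375
    kbt_pn_nm: float = KBT_PN_NM
    duration_s: float = 300.0
    sample_interval_s: float = 1.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.time_step_s <= 0:
            raise ConfigError("simulation.time_step_s must be > 0")
        if self.nucleus_radius_um <= 0:
            raise ConfigError("simulation.nucleus_radius_um must be > 0")
        if self.kbt_pn_nm <= 0:
            raise ConfigError("simulation.kbt_pn_nm must be > 0")
        if self.duration_s <= 0:
            raise ConfigError("simulation.duration_s must be > 0")
        if self.sample_interval_s <= 0:
            raise ConfigError("simulation.sample_interval_s must be > 0")


@dataclass
class SPBParams:
    """Spindle-pole body size, anchoring, and surface mobility."""

    diameter_um: float = 0.1625
    bridge_size_nm: float = 75.0
    tether_spring_pn_nm: float = 0.6625
    tether_rest_length_nm: float = 50.0
    diffusion_trans_um2_s: float = 4.5e-4
    diffusion_rot_s: float = 0.0170
    linkage_time_s: float = 5.0
    n_nucleation_sites: int = 14

    def validate(self) -> None:
        if self.diameter_um <= 0:
            raise ConfigError("spb.diameter_um must be > 0")
        if self.n_nucleation_sites < 1:
            raise ConfigError("spb.n_nucleation_sites must be >= 1")
        if self.diffusion_trans_um2_s < 0 or self.diffusion_rot_s < 0:
            raise ConfigError("spb diffusion coefficients must be >= 0")


@dataclass
class EnvelopeParams:
    """Nuclear envelope: rigid sphere or soft (deformable) radial potential."""

    mode: str = "rigid"  # "rigid" | "soft"
    mobility_radial_um_s_pn: float = 0.05
    mobility_tangent_um_s_pn: float = 0.11
    tube_radius_nm: float = 87.7
    mt_wall_force_pn: float = 2.5
    spb_wall_force_pn: float = 17.0
    soft_tether_spring_pn_nm: float = 6.625

    def validate(self) -> None:
        if self.mode not in ("rigid", "soft"):
            raise ConfigError(f"envelope.mode must be 'rigid' or 'soft', got {self.mode!r}")
        if self.mt_wall_force_pn < 0 or self.spb_wall_force_pn < 0:
            raise ConfigError("envelope wall forces must be >= 0")
        if self.tube_radius_nm <= 0:
            raise ConfigError("envelope.tube_radius_nm must be > 0")


@dataclass
class MTParams:
    """Microtubule geometry and dynamic instability."""

    diameter_nm: float = 25.0
    catastrophe_force_constant_inv_pn: float = 0.5  # alpha_c
    growth_speed_um_min: float = 4.1
    shrink_speed_um_min: float = 6.7
    catastrophe_freq_per_min: float = 3.994
    rescue_freq_per_min: float = 0.157
    stab_growth: float = 1.54
    stab_shrink: float = 0.094
    stab_catastrophe: float = 0.098
    stab_rescue: float = 18.0
    stabilization_enabled: bool = True
    stabilization_length_nm: float = 16.0
    min_length_nm: float = 75.0
    viscosity_pa_s: float = 1.0

    def validate(self) -> None:
        for name in ("growth_speed_um_min", "shrink_speed_um_min",
                     "catastrophe_freq_per_min", "rescue_freq_per_min"):
            if getattr(self, name) < 0:
                raise ConfigError(f"microtubule.{name} must be >= 0")
        if self.min_length_nm <= 0:
            raise ConfigError("microtubule.min_length_nm must be > 0")
        if self.viscosity_pa_s <= 0:
            raise ConfigError("microtubule.viscosity_pa_s must be > 0")


@dataclass
class Kinesin5Params:
    """Bidirectional plus-end sliding motor (Cut7-like)."""

    number: int = 174
    association_per_um_site: float = 90.9
    c2_inv_nm: float = 0.4
    spring_pn_nm: float = 0.3
    v_single_nm_s: float = -100.0
    v_polar_nm_s: float = -50.0
    v_antipolar_nm_s: float = 8.0
    k1_s: float = 0.11
    k2_s: float = 0.055
    rest_length_nm: float = 53.0
    stall_force_pn: float = 5.0
    xc_nm: float = 1.5

    def validate(self) -> None:
        if self.number < 0:
            raise ConfigError("kinesin5.number must be >= 0")
        if self.stall_force_pn <= 0:
            raise ConfigError("kinesin5.stall_force_pn must be > 0")


@dataclass
class Kinesin14Params:
    """Minus-end walking motor with one motile and one diffusive head."""

    number: int = 230
    association_motor_per_um_site: float = 22.727
    association_passive_per_um_site: float = 22.727
    c2_motor_inv_nm: float = 0.1
    c2_passive_inv_nm: float = 0.1
    spring_pn_nm: float = 0.3
    v_motor_nm_s: float = -50.0
    d_passive_um2_s: float = 0.1
    k1_motor_s: float = 0.11
    k1_passive_s: float = 0.1
    k2_motor_s: float = 0.055
    k2_passive_s: float = 0.05
    rest_length_nm: float = 53.0
    stall_force_pn: float = 5.0
    xc_nm: float = 4.8

    def validate(self) -> None:
        if self.number < 0:
            raise ConfigError("kinesin14.number must be >= 0")
        if self.stall_force_pn <= 0:
            raise ConfigError("kinesin14.stall_force_pn must be > 0")


@dataclass
class CrosslinkerParams:
    """Passive antiparallel-preferring crosslinker (Ase1-like)."""

    number: int = 657
    association_per_um_site: float = 90.9
    c2_inv_nm: float = 0.4
    spring_pn_nm: float = 0.207
    d_single_um2_s: float = 0.1
    d_double_um2_s: float = 6.7e-3
    k1_s: float = 0.1
    k2_s: float = 0.05
    parallel_affinity: float = 0.33
    xc_nm: float = 2.1
    rest_length_nm: float = 53.0

    def validate(self) -> None:
        if self.number < 0:
            raise ConfigError("crosslinker.number must be >= 0")
        if not 0 <= self.parallel_affinity <= 1:
            raise ConfigError("crosslinker.parallel_affinity must be in [0, 1]")


@dataclass
class ChromosomeParams:
    """Kinetochore plates, interkinetochore spring, and pericentric chromatin."""

    count: int = 3
    kc_length_nm: float = 150.0
    kc_width_nm: float = 50.0
    site_spacing_nm: float = 40.0
    kc_drag_trans_pn_s_um: float = 3.51
    kc_drag_rot_pn_um_s: float = 0.165
    kc_catastrophe_enh_inv_pn: float = 0.5
    inter_kc_rest_nm: float = 100.0
    inter_kc_spring_pn_um: float = 39.0
    inter_kc_rot_pn_nm: float = 1850.0
    inter_kc_align_pn_nm: float = 1850.0
    chromatin_length_nm: float = 200.0
    chromatin_diameter_nm: float = 75.0
    kc_chromatin_offset_nm: float = 37.5
    chromatin_mt_amplitude_pn_nm: float = 1.0

    def validate(self) -> None:
        if self.count < 1:
            raise ConfigError("chromosome.count must be >= 1")
        if self.inter_kc_spring_pn_um < 0 or self.inter_kc_rot_pn_nm < 0 \
                or self.inter_kc_align_pn_nm < 0:
            raise ConfigError("chromosome interkinetochore stiffnesses must be >= 0")


@dataclass
class AttachmentParams:
    """Kinetochore-MT attachment factors: kinetics, springs, and force factors."""

    spring_pn_nm: float = 0.088
    rest_length_nm: float = 54.0
    angular_stiffness_pn_nm: tuple = (4.1, 41.0, 410.0, 410.0)
    kmc_substeps: int = 10
    tip_length_nm: float = 25.0
    tip_concentration_inv_nm: float = 40.0
    side_concentration_inv_nm: float = 0.4
    k_tip_assembling_s: float = 1.0e-4
    k_tip_disassembling_s: float = 0.03
    k_side_s: float = 0.03
    xc_tip_assembling_nm: float = 1.0
    xc_tip_disassembling_nm: float = -3.9
    xc_side_nm: float = -0.37
    angular_factor: float = 0.013  # chi_c
    motor_speed_nm_s: float = 50.0
    stall_force_pn: float = 5.0
    d_tip_um2_s: float = 0.0012
    d_side_um2_s: float = 0.018
    tip_tracking: float = 0.25
    tip_enhanced_catastrophe: float = 4.0
    misaligned_destabilization: float = 70.0
    f_growth_pn: float = 8.4
    f_shrink_pn: float = -3.0
    f_catastrophe_pn: float = -2.3
    f_rescue_pn: float = 6.4
    max_growth_um_min: float = 30.0

    def validate(self) -> None:
        if len(self.angular_stiffness_pn_nm) != 4:
            raise ConfigError("attachment.angular_stiffness_pn_nm needs 4 values "
                              "(occupancy 0..3)")
        if self.kmc_substeps < 1:
            raise ConfigError("attachment.kmc_substeps must be >= 1")
        if self.misaligned_destabilization < 1:
            raise ConfigError("attachment.misaligned_destabilization must be >= 1")
        if not 0 <= self.tip_tracking <= 1:
            raise ConfigError("attachment.tip_tracking must be in [0, 1]")


@dataclass
class ErrorCorrectionParams:
    """Which error-correction variant is active."""

    mode: str = "misaligned"  # "misaligned" | "force"
    characteristic_force_pn: float = 1.67

    def validate(self) -> None:
        if self.mode not in ("misaligned", "force"):
            raise ConfigError(
                f"error_correction.mode must be 'misaligned' or 'force', got {self.mode!r}")
        if self.characteristic_force_pn <= 0:
            raise ConfigError("error_correction.characteristic_force_pn must be > 0")


@dataclass
class AnaphaseParams:
    """Checkpoint-like trigger and anaphase-A rules."""

    enabled: bool = False
    sac_time_min: float = 4.45
    attachment_rate_s: float = 7.0e-5
    depoly_speed_um_min: float = 2.2

    def validate(self) -> None:
        if self.sac_time_min <= 0:
            raise ConfigError("anaphase.sac_time_min must be > 0")


@dataclass
class NumericsParams:
    """Purely numerical choices (not biology): steric stiffness, clamps, cadences."""

    wall_spring_pn_nm: float = 1.0
    wca_epsilon_kbt: float = 1.0
    force_clamp_pn: float = 200.0
    segment_nm: float = 4.0
    binding_refresh_steps: int = 100
    kinetics_stride: int = 5
    lattice_density_inv_nm: float = 1.625  # 13 protofilaments / 8 nm dimer
    tracking_quantum_nm: float = 8.0

    def validate(self) -> None:
        if self.binding_refresh_steps < 1:
            raise ConfigError("numerics.binding_refresh_steps must be >= 1")
        if self.kinetics_stride < 1:
            raise ConfigError("numerics.kinetics_stride must be >= 1")
        if self.segment_nm <= 0:
            raise ConfigError("numerics.segment_nm must be > 0")


_BLOCKS = {
    "simulation": SimulationParams,
    "spb": SPBParams,
    "envelope": EnvelopeParams,
    "microtubule": MTParams,
    "kinesin5": Kinesin5Params,
    "kinesin14": Kinesin14Params,
    "crosslinker": CrosslinkerParams,
    "chromosome": ChromosomeParams,
    "attachment": AttachmentParams,
    "error_correction": ErrorCorrectionParams,
    "anaphase": AnaphaseParams,
    "numerics": NumericsParams,
}


@dataclass
class ModelParams:
    """Full parameter set for one simulation run."""

    simulation: SimulationParams = field(default_factory=SimulationParams)
    spb: SPBParams = field(default_factory=SPBParams)
    envelope: EnvelopeParams = field(default_factory=EnvelopeParams)
    microtubule: MTParams = field(default_factory=MTParams)
    kinesin5: Kinesin5Params = field(default_factory=Kinesin5Params)
    kinesin14: Kinesin14Params = field(default_factory=Kinesin14Params)
    crosslinker: CrosslinkerParams = field(default_factory=CrosslinkerParams)
    chromosome: ChromosomeParams = field(default_factory=ChromosomeParams)
    attachment: AttachmentParams = field(default_factory=AttachmentParams)
    error_correction: ErrorCorrectionParams = field(default_factory=ErrorCorrectionParams)
    anaphase: AnaphaseParams = field(default_factory=AnaphaseParams)
    numerics: NumericsParams = field(default_factory=NumericsParams)

    def validate(self) -> "ModelParams":
        for name in _BLOCKS:
            getattr(self, name).validate()
        return self

    # -- flat internal-unit vector for the engine ---------------------------

    def pack(self) -> np.ndarray:
        """Convert to the flat internal-unit (pN/nm/s) vector for the kernel."""
        self.validate()
        s, b, e = self.simulation, self.spb, self.envelope
        m, k5, k14, xl = self.microtubule, self.kinesin5, self.kinesin14, self.crosslinker
        c, a, ec, an, nu = (self.chromosome, self.attachment, self.error_correction,
                            self.anaphase, self.numerics)
        kr = a.angular_stiffness_pn_nm
        vals = {
            "dt": s.time_step_s,
            "radius": s.nucleus_radius_um * 1000.0,
            "kbt": s.kbt_pn_nm,
            # SPB
            "spb_diam": b.diameter_um * 1000.0,
            "bridge": b.bridge_size_nm,
            "spb_k0": b.tether_spring_pn_nm,
            "spb_r0": b.tether_rest_length_nm,
            "spb_dt": b.diffusion_trans_um2_s * UM2_S_TO_NM2_S,
            "spb_dr": b.diffusion_rot_s,
            "tau_link": b.linkage_time_s,
            "n_sites": float(b.n_nucleation_sites),
            # envelope
            "soft_mode": 1.0 if e.mode == "soft" else 0.0,
            "mob_rad": e.mobility_radial_um_s_pn * 1000.0,
            "mob_tan": e.mobility_tangent_um_s_pn * 1000.0,
            "ftube": e.tube_radius_nm,
            "f_mt_wall": e.mt_wall_force_pn,
            "f_spb_wall": e.spb_wall_force_pn,
            "spb_k0_soft": e.soft_tether_spring_pn_nm,
            # MT
            "mt_diam": m.diameter_nm,
            "alpha_c": m.catastrophe_force_constant_inv_pn,
            "vg0": m.growth_speed_um_min * UM_MIN_TO_NM_S,
            "vs0": m.shrink_speed_um_min * UM_MIN_TO_NM_S,
            "fc0": m.catastrophe_freq_per_min * PER_MIN_TO_PER_S,
            "fr0": m.rescue_freq_per_min * PER_MIN_TO_PER_S,
            "svg": m.stab_growth,
            "svs": m.stab_shrink,
            "sfc": m.stab_catastrophe,
            "sfr": m.stab_rescue,
            "stab_on": 1.0 if m.stabilization_enabled else 0.0,
            "s_l": m.stabilization_length_nm,
            "l_min": m.min_length_nm,
            "eta": m.viscosity_pa_s * 1.0e-6,  # Pa s -> pN s / nm^2
            # kinesin-5
            "k5_n": float(k5.number),
            "k5_ka": k5.association_per_um_site,
            "k5_c2": k5.c2_inv_nm,
            "k5_k": k5.spring_pn_nm,
            "k5_v0": k5.v_single_nm_s,
            "k5_v0p": k5.v_polar_nm_s,
            "k5_v0ap": k5.v_antipolar_nm_s,
            "k5_k1": k5.k1_s,
            "k5_k2": k5.k2_s,
            "k5_r0": k5.rest_length_nm,
            "k5_fs": k5.stall_force_pn,
            "k5_xc": k5.xc_nm,
            # kinesin-14
            "k14_n": float(k14.number),
            "k14_ka_m": k14.association_motor_per_um_site,
            "k14_ka_d": k14.association_passive_per_um_site,
            "k14_c2m": k14.c2_motor_inv_nm,
            "k14_c2d": k14.c2_passive_inv_nm,
            "k14_k": k14.spring_pn_nm,
            "k14_v0m": k14.v_motor_nm_s,
            "k14_dd": k14.d_passive_um2_s * UM2_S_TO_NM2_S,
            "k14_k1m": k14.k1_motor_s,
            "k14_k1d": k14.k1_passive_s,
            "k14_k2m": k14.k2_motor_s,
            "k14_k2d": k14.k2_passive_s,
            "k14_r0": k14.rest_length_nm,
            "k14_fs": k14.stall_force_pn,
            "k14_xc": k14.xc_nm,
            # crosslinker
            "xl_n": float(xl.number),
            "xl_ka": xl.association_per_um_site,
            "xl_c2": xl.c2_inv_nm,
            "xl_k": xl.spring_pn_nm,
            "xl_dsb": xl.d_single_um2_s * UM2_S_TO_NM2_S,
            "xl_ddb": xl.d_double_um2_s * UM2_S_TO_NM2_S,
            "xl_k1": xl.k1_s,
            "xl_k2": xl.k2_s,
            "xl_paff": xl.parallel_affinity,
            "xl_xc": xl.xc_nm,
            "xl_r0": xl.rest_length_nm,
            # chromosome / kinetochore
            "n_chrom": float(c.count),
            "kc_len": c.kc_length_nm,
            "kc_wid": c.kc_width_nm,
            "site_sep": c.site_spacing_nm,
            "kc_gt": c.kc_drag_trans_pn_s_um / 1000.0,  # pN s / nm
            "kc_gr": c.kc_drag_rot_pn_um_s * 1000.0,    # pN nm s
            "kc_fc_enh": c.kc_catastrophe_enh_inv_pn,
            "rc0": c.inter_kc_rest_nm,
            "kappa_c": c.inter_kc_spring_pn_um / 1000.0,  # pN / nm
            "kappa_cu": c.inter_kc_rot_pn_nm,
            "kappa_cv": c.inter_kc_align_pn_nm,
            "chrom_len": c.chromatin_length_nm,
            "chrom_diam": c.chromatin_diameter_nm,
            "kc_offset": c.kc_chromatin_offset_nm,
            "a_cmt": c.chromatin_mt_amplitude_pn_nm,
            # attachment factors
            "af_km": a.spring_pn_nm,
            "af_r0": a.rest_length_nm,
            "af_kr0": kr[0],
            "af_kr1": kr[1],
            "af_kr2": kr[2],
            "af_kr3": kr[3],
            "n_kmc": float(a.kmc_substeps),
            "tip_len": a.tip_length_nm,
            "c_tip": a.tip_concentration_inv_nm,
            "c_side": a.side_concentration_inv_nm,
            "k_tip_a": a.k_tip_assembling_s,
            "k_tip_d": a.k_tip_disassembling_s,
            "k_side": a.k_side_s,
            "xc_ta": a.xc_tip_assembling_nm,
            "xc_td": a.xc_tip_disassembling_nm,
            "xc_s": a.xc_side_nm,
            "chi_c": a.angular_factor,
            "af_v": a.motor_speed_nm_s,
            "af_fs": a.stall_force_pn,
            "d_tip": a.d_tip_um2_s * UM2_S_TO_NM2_S,
            "d_side": a.d_side_um2_s * UM2_S_TO_NM2_S,
            "f_track": a.tip_tracking,
            "s_dam1": a.tip_enhanced_catastrophe,
            "s_abk": a.misaligned_destabilization,
            "f_vg": a.f_growth_pn,
            "f_vs": a.f_shrink_pn,
            "f_fc": a.f_catastrophe_pn,
            "f_fr": a.f_rescue_pn,
            "v_mt_max": a.max_growth_um_min * UM_MIN_TO_NM_S,
            # error correction
            "ec_mode": 1.0 if ec.mode == "force" else 0.0,
            "fec0": ec.characteristic_force_pn,
            # anaphase
            "ana_on": 1.0 if an.enabled else 0.0,
            "tau_sac": an.sac_time_min * 60.0,
            "k_ana": an.attachment_rate_s,
            "v_ana": an.depoly_speed_um_min * UM_MIN_TO_NM_S,
            # numerics
            "wall_k": nu.wall_spring_pn_nm,
            "wca_eps": nu.wca_epsilon_kbt * s.kbt_pn_nm,
            "f_clamp": nu.force_clamp_pn,
            "ds_seg": nu.segment_nm,
            "n_refresh": float(nu.binding_refresh_steps),
            "kin_stride": float(nu.kinetics_stride),
            "site_dens": nu.lattice_density_inv_nm,
            "track_quant": nu.tracking_quantum_nm,
        }
        if list(vals.keys()) != PARAM_NAMES:
            raise AssertionError("parameter packing order drifted from PARAM_NAMES")
        return np.array([vals[k] for k in PARAM_NAMES], dtype=np.float64)

    # -- dict / yaml round-trip ---------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        mp = cls()
        for block, payload in d.items():
            if block not in _BLOCKS:
                raise ConfigError(f"unknown config section {block!r}")
            if payload is None:
                continue
            if not isinstance(payload, dict):
                raise ConfigError(f"config section {block!r} must be a mapping")
            target = getattr(mp, block)
            valid = {f.name for f in dataclasses.fields(target)}
            for key, value in payload.items():
                if key not in valid:
                    raise ConfigError(f"unknown key {block}.{key}")
                current = getattr(target, key)
                if isinstance(current, bool):
                    if not isinstance(value, bool):
                        raise ConfigError(f"{block}.{key} must be a boolean")
                elif isinstance(current, int) and not isinstance(current, bool):
                    if not isinstance(value, int):
                        raise ConfigError(f"{block}.{key} must be an integer")
                elif isinstance(current, float):
                    if not isinstance(value, (int, float)):
                        raise ConfigError(f"{block}.{key} must be a number")
                elif isinstance(current, tuple):
                    if not isinstance(value, (list, tuple)):
                        raise ConfigError(f"{block}.{key} must be a list")
                    value = tuple(float(v) for v in value)
                setattr(target, key, value)
        mp.validate()
        return mp

    def apply_overrides(self, overrides: dict[str, Any]) -> "ModelParams":
        """Apply ``{"block.key": value}`` overrides in place; returns self."""
        for dotted, value in overrides.items():
            block, _, key = dotted.partition(".")
            if block not in _BLOCKS or not key:
                raise ConfigError(f"unknown override {dotted!r}")
            target = getattr(self, block)
            if key not in {f.name for f in dataclasses.fields(target)}:
                raise ConfigError(f"unknown override {dotted!r}")
            if isinstance(getattr(target, key), tuple):
                value = tuple(float(v) for v in value)
            setattr(target, key, value)
        self.validate()
        return self


# Canonical slot order of the packed parameter vector.  The engine resolves
# these names to integer constants at import time.
PARAM_NAMES = [
    "dt", "radius", "kbt",
    "spb_diam", "bridge", "spb_k0", "spb_r0", "spb_dt", "spb_dr", "tau_link", "n_sites",
    "soft_mode", "mob_rad", "mob_tan", "ftube", "f_mt_wall", "f_spb_wall",
    "spb_k0_soft",
    "mt_diam", "alpha_c", "vg0", "vs0", "fc0", "fr0", "svg", "svs", "sfc",
    "sfr", "stab_on", "s_l", "l_min", "eta",
    "k5_n", "k5_ka", "k5_c2", "k5_k", "k5_v0", "k5_v0p", "k5_v0ap", "k5_k1",
    "k5_k2", "k5_r0", "k5_fs", "k5_xc",
    "k14_n", "k14_ka_m", "k14_ka_d", "k14_c2m", "k14_c2d", "k14_k", "k14_v0m",
    "k14_dd", "k14_k1m", "k14_k1d", "k14_k2m", "k14_k2d", "k14_r0", "k14_fs",
    "k14_xc",
    "xl_n", "xl_ka", "xl_c2", "xl_k", "xl_dsb", "xl_ddb", "xl_k1", "xl_k2",
    "xl_paff", "xl_xc", "xl_r0",
    "n_chrom", "kc_len", "kc_wid", "site_sep", "kc_gt", "kc_gr", "kc_fc_enh",
    "rc0", "kappa_c", "kappa_cu", "kappa_cv", "chrom_len", "chrom_diam",
    "kc_offset", "a_cmt",
    "af_km", "af_r0", "af_kr0", "af_kr1", "af_kr2", "af_kr3", "n_kmc",
    "tip_len", "c_tip", "c_side", "k_tip_a", "k_tip_d", "k_side", "xc_ta",
    "xc_td", "xc_s", "chi_c", "af_v", "af_fs", "d_tip", "d_side", "f_track",
    "s_dam1", "s_abk", "f_vg", "f_vs", "f_fc", "f_fr", "v_mt_max",
    "ec_mode", "fec0",
    "ana_on", "tau_sac", "k_ana", "v_ana",
    "wall_k", "wca_eps", "f_clamp", "ds_seg", "n_refresh", "kin_stride",
    "site_dens", "track_quant",
]

PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}


def load_config(path) -> ModelParams:
    """Load and validate a YAML configuration file.

    Unspecified keys take the reference-model defaults; unknown sections or
    keys, wrong types, and out-of-range values raise :class:`ConfigError`
    naming the offending key.
    """
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of config file must be a mapping of sections")
    return ModelParams.from_dict(raw)


def save_config(params: ModelParams, path) -> None:
    """Write the full parameter set (all keys explicit) as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
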