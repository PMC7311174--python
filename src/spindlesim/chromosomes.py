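"""Chromosome and kinetochore mechanics and attachment kinetics.

Each chromosome is a pair of sister kinetochores — thin rectangular plates
carrying three MT attachment factors each — linked by linear and angular
springs, backed by a pericentric-chromatin spherocylinder.  The three
biorientation mechanisms live here: progressive restriction of attachment
angle (occupancy-dependent angular stiffness), misaligned destabilization
(accelerated detachment for non-amphitelic chromosomes), and
interkinetochore-tension-dependent attachment kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import _formulas as f
from .params import KBT_PN_NM, AttachmentParams, ChromosomeParams


class AttachMode(Enum):
    UNBOUND = 0
    LATERAL = 1
    END_ON = 2


class ChromosomeState(Enum):
    LOST = 0
    MONOTELIC = 1
    SYNTELIC = 2
    AMPHITELIC = 3
    MEROTELIC = 4


@dataclass
class Kinetochore:
    """Plate pose: center, outward normal, and long (site) axis."""

    position: np.ndarray
    normal: np.ndarray
    long_axis: np.ndarray
    length_nm: float = 150.0
    width_nm: float = 50.0
    site_spacing_nm: float = 40.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        self.normal /= np.linalg.norm(self.normal)
        t = np.asarray(self.long_axis, dtype=float)
        t = t - np.dot(t, self.normal) * self.normal
        self.long_axis = t / np.linalg.norm(t)

    def site_positions(self) -> np.ndarray:
        """The three collinear attachment sites, spaced along the plate."""
        offsets = np.array([-1.0, 0.0, 1.0]) * self.site_spacing_nm
        return self.position[None, :] + offsets[:, None] * self.long_axis[None, :]


# ---------------------------------------------------------------------------
# Progressive restriction and attachment kinetics
# ---------------------------------------------------------------------------

def progressive_restriction_stiffness(occupancy: int,
                                      p: AttachmentParams | None = None) -> float:
    """Angular spring constant kappa_AF,r,n for the given site occupancy.

    Used both in the Boltzmann factor exp(-kappa theta^2 / 2 kBT) gating
    new attachments and as the aligning torque stiffness on bound
    attachments.  Occupancy 0 is permissive (4.1 pN nm); each bound MT
    narrows the accepted cone, saturating at 410 pN nm.
    """
    p = p or AttachmentParams()
    if not 0 <= occupancy <= 3:
        raise ValueError("occupancy must be in {0, 1, 2, 3}")
    return p.angular_stiffness_pn_nm[occupancy]


def af_attach_rate(mode: AttachMode, tether_energy: float, angle: float,
                   occupancy: int, tip_state: str = "assembling",
                   tip_occupied: bool = False,
                   p: AttachmentParams | None = None,
                   kbt: float = KBT_PN_NM) -> float:
    """Per-unit-length attachment rate density (nm^-1 s^-1) for a candidate.

    rate = c_mode * k_mode * exp(-U_tether/kBT) * exp(-kappa_n theta^2 / 2 kBT),
    where theta is the angle between the MT axis (pointing into the plate)
    and the plate normal.  The engine integrates this density over the
    candidate length (lateral segments, or the tip region for end-on).
    End-on binding to an already-occupied plus end is forbidden (at most
    one attachment factor per MT tip).
    """
    p = p or AttachmentParams()
    if mode == AttachMode.END_ON:
        if tip_occupied:
            return 0.0
        c = p.tip_concentration_inv_nm
        k = (p.k_tip_assembling_s if tip_state == "assembling"
             else p.k_tip_disassembling_s)
    elif mode == AttachMode.LATERAL:
        c = p.side_concentration_inv_nm
        k = p.k_side_s
    else:
        raise ValueError("candidate mode must be LATERAL or END_ON")
    kappa = progressive_restriction_stiffness(occupancy, p)
    return (c * k * f.binding_weight(tether_energy, kbt)
            * np.exp(-kappa * angle * angle / (2.0 * kbt)))


def af_detach_rate(mode: AttachMode, tension: float, angle: float,
                   occupancy: int, amphitelic: bool,
                   tip_state: str = "assembling",
                   ec_mode: str = "misaligned", inter_kc_force: float = 0.0,
                   p: AttachmentParams | None = None,
                   fec0: float = 1.67, kbt: float = KBT_PN_NM) -> float:
    """Detachment rate of a bound attachment factor.

    Base rate and Bell characteristic distance depend on the mode and on
    the MT tip state (end-on attachment to a depolymerizing tip is a catch
    bond, xc = -3.9 nm).  An angular penalty exp(chi_c kappa theta^2/2kBT)
    destabilizes high-angle attachments.  Error correction enters as a
    multiplicative factor: the misaligned-destabilization factor for any
    attachment of a non-amphitelic chromosome, or the interkinetochore
    force stabilization 2^(-F/F_EC,0) in the force-dependent variant.
    """
    p = p or AttachmentParams()
    if mode == AttachMode.END_ON:
        if tip_state == "assembling":
            k0, xc = p.k_tip_assembling_s, p.xc_tip_assembling_nm
        else:
            k0, xc = p.k_tip_disassembling_s, p.xc_tip_disassembling_nm
    elif mode == AttachMode.LATERAL:
        k0, xc = p.k_side_s, p.xc_side_nm
    else:
        raise ValueError("attachment factor is not bound")
    kappa = progressive_restriction_stiffness(occupancy, p)
    rate = (f.bell_rate(k0, tension, xc, kbt)
            * np.exp(p.angular_factor * kappa * angle * angle / (2.0 * kbt)))
    if ec_mode == "misaligned":
        if not amphitelic:
            rate *= p.misaligned_destabilization
    elif ec_mode == "force":
        rate *= interkinetochore_stabilization(inter_kc_force, fec0)
    else:
        raise ValueError(f"unknown error-correction mode {ec_mode!r}")
    return rate


def interkinetochore_stabilization(inter_kc_force: float,
                                   fec0: float = 1.67) -> float:
    """Turnover multiplier 2^(-F/F_EC,0) of the force-dependent EC variant.

    At the characteristic interkinetochore force the turnover of all
    attachments of both sisters is halved; compression contributes nothing.
    """
    if inter_kc_force < 0:
        inter_kc_force = 0.0
    return 2.0 ** (-inter_kc_force / fec0)


def tip_track(delta_length: float, rng: np.random.Generator,
              f_track: float = 0.25, quantum_nm: float = 8.0) -> bool:
    """Does an end-on attachment remain tip-bound through this length change?

    Shrinkage: the attachment moves with the tip (processive end-coupling),
    always True.  Growth: each tubulin-dimer length (8 nm) of growth is a
    tracking opportunity at which the factor stays at the advancing tip
    with probability ``f_track``, else it converts to a lateral attachment
    at its current position.
    """
    if delta_length <= 0.0:
        return True
    n_ops = int(np.ceil(delta_length / quantum_nm))
    for _ in range(n_ops):
        if rng.random() >= f_track:
            return False
    return True


def af_motor_step(arc_pos: float, opposing_force: float, dt: float,
                  rng: np.random.Generator,
                  p: AttachmentParams | None = None,
                  kbt: float = KBT_PN_NM) -> float:
    """Advance a lateral attachment along its MT by motor stepping + diffusion.

    The attachment factor contains a plus-end-directed motor (50 nm/s,
    5 pN stall) and diffuses with the side-binding diffusion constant.
    Returns the new arc position (conversion to end-on at the tip is the
    engine's job).
    """
    p = p or AttachmentParams()
    v = f.force_velocity(p.motor_speed_nm_s, opposing_force, p.stall_force_pn)
    d_side = p.d_side_um2_s * 1.0e6
    return (arc_pos + v * dt
            + np.sqrt(2.0 * d_side * dt) * rng.standard_normal())


# ---------------------------------------------------------------------------
# Attachment-state classification
# ---------------------------------------------------------------------------

def classify_attachment(sister_a_poles, sister_b_poles) -> ChromosomeState:
    """Classify a chromosome from the pole identities of its attached MTs.

    Arguments are iterables of pole labels (one entry per attached MT) for
    each sister.  Lost: no attachments at all; merotelic: any single sister
    holds MTs from both poles; amphitelic: each sister holds MTs from
    exactly one pole and the poles differ; syntelic: both sisters hold MTs
    from one common pole; monotelic: only one sister is attached.
    """
    a = set(sister_a_poles)
    b = set(sister_b_poles)
    if not a and not b:
        return ChromosomeState.LOST
    if len(a) > 1 or len(b) > 1:
        return ChromosomeState.MEROTELIC
    if not a or not b:
        return ChromosomeState.MONOTELIC
    return ChromosomeState.AMPHITELIC if a != b else ChromosomeState.SYNTELIC


# ---------------------------------------------------------------------------
# Interkinetochore mechanics
# ---------------------------------------------------------------------------

def _restoring_torque(a: np.ndarray, target: np.ndarray, kappa: float):
    """Torque kappa * theta about (a x target) rotating a toward target."""
    c = float(np.clip(np.dot(a, target), -1.0, 1.0))
    theta = np.arccos(c)
    axis = np.cross(a, target)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        return np.zeros(3)
    return kappa * theta * axis / n


def interkinetochore_forces(kc_a: Kinetochore, kc_b: Kinetochore,
                            p: ChromosomeParams | None = None):
    """Spring forces and torques linking sister kinetochores.

    Linear spring (kappa_C, rest length R_C,0) acts along the sister-sister
    axis.  Each plate normal is restored toward anti-alignment with the
    axis pointing at its sister (plates face away from each other,
    stiffness kappa_C,u); the plate long axes are restored toward mutual
    alignment (kappa_C,v).  Returns
    ``(force_on_a, torque_on_a, torque_on_b)`` with the force on b equal
    and opposite.
    """
    p = p or ChromosomeParams()
    dv = kc_b.position - kc_a.position
    r = np.linalg.norm(dv)
    if r < 1e-9:
        return np.zeros(3), np.zeros(3), np.zeros(3)
    u = dv / r  # a -> b
    k_lin = p.inter_kc_spring_pn_um / 1000.0  # pN/nm
    force_on_a = k_lin * (r - p.inter_kc_rest_nm) * u
    # plate normals face away from the sister
    tq_a = _restoring_torque(kc_a.normal, -u, p.inter_kc_rot_pn_nm)
    tq_b = _restoring_torque(kc_b.normal, u, p.inter_kc_rot_pn_nm)
    # long axes mutually aligned (sign-free: align toward the nearer direction)
    tb = kc_b.long_axis if np.dot(kc_a.long_axis, kc_b.long_axis) >= 0 \
        else -kc_b.long_axis
    tq_align = _restoring_torque(kc_a.long_axis, tb, p.inter_kc_align_pn_nm)
    tq_a = tq_a + tq_align
    tq_b = tq_b - tq_align
    return force_on_a, tq_a, tq_b


def interkinetochore_tension(kc_a: Kinetochore, kc_b: Kinetochore,
                             p: ChromosomeParams | None = None) -> float:
    """Instantaneous tension (pN, >= 0) in the linear sister spring."""
    p = p or ChromosomeParams()
    r = float(np.linalg.norm(kc_b.position - kc_a.position))
    k_lin = p.inter_kc_spring_pn_um / 1000.0
    return max(0.0, k_lin * (r - p.inter_kc_rest_nm))


def interkinetochore_energy(kc_a: Kinetochore, kc_b: Kinetochore,
                            p: ChromosomeParams | None = None) -> float:
    """Total elastic energy of the sister linkage (pN nm); used for
    finite-difference consistency checks of the forces and torques."""
    p = p or ChromosomeParams()
    dv = kc_b.position - kc_a.position
    r = np.linalg.norm(dv)
    u = dv / r
    k_lin = p.inter_kc_spring_pn_um / 1000.0
    e = 0.5 * k_lin * (r - p.inter_kc_rest_nm) ** 2
    for kc, target in ((kc_a, -u), (kc_b, u)):
        c = float(np.clip(np.dot(kc.normal, target), -1.0, 1.0))
        e += 0.5 * p.inter_kc_rot_pn_nm * np.arccos(c) ** 2
    c = abs(float(np.clip(np.dot(kc_a.long_axis, kc_b.long_axis), -1.0, 1.0)))
    e += 0.5 * p.inter_kc_align_pn_nm * np.arccos(c) ** 2
    return e
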