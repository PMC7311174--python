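"""Statistical mechanics of binding and unbinding.

All motor, crosslinker, and kinetochore-attachment state changes go
through the same primitives: Boltzmann-weighted association, Bell-law
force-dependent dissociation, linear force-velocity stepping, and
per-timestep kinetic Monte Carlo event sampling with probability
1 - exp(-k dt).  Solution species are treated as a well-mixed reservoir
(their free diffusion is fast compared to the timestep).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _formulas as f
from .params import KBT_PN_NM

#: molar concentration (uM) of one molecule per nm^3
_UM_PER_MOLECULE_PER_NM3 = 1.0e30 / 6.02214076e23  # uM per (molecule / nm^3)


@dataclass
class BindingKinetics:
    """Kinetic constants of one binding species (Table-style units)."""

    association_per_um_site: float = 90.9
    c2_inv_nm: float = 0.4
    k1_s: float = 0.11
    k2_s: float = 0.055
    spring_pn_nm: float = 0.3
    rest_length_nm: float = 53.0
    xc_nm: float = 1.5
    stall_force_pn: float = 5.0
    v0_nm_s: float = -100.0


def bell_rate(k0: float, force: float, xc: float, kbt: float = KBT_PN_NM) -> float:
    """Force-dependent rate k0 exp(F xc / kBT).

    ``force`` is the scalar tether tension (negative values, i.e.
    compression, are treated as zero).  A negative characteristic distance
    ``xc`` gives catch-bond behavior: the rate decreases under load.
    """
    if k0 < 0:
        raise ValueError("k0 must be >= 0")
    return f.bell_rate(k0, force, xc, kbt)


def force_velocity(v0: float, parallel_force: float, fs: float) -> float:
    """Linear force-velocity v0 (1 - f/Fs), clamped factor in [0, 2]."""
    if fs <= 0:
        raise ValueError("stall force must be > 0")
    return f.force_velocity(v0, parallel_force, fs)


def binding_weight(energy: float, kbt: float = KBT_PN_NM) -> float:
    """Boltzmann weight exp(-U/kBT) of a candidate tether configuration."""
    return f.binding_weight(energy, kbt)


def kmc_sample_events(rates, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Sample independent per-timestep events.

    Each event with rate k fires with probability 1 - exp(-k dt); returns a
    boolean array.  Attachment-factor events are sampled by the engine with
    Nkmc substeps of dt/Nkmc using this same rule.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    p = 1.0 - np.exp(-rates * dt)
    return rng.random(rates.shape) < p


def site_concentration_um(total_mt_length_nm: float, nucleus_radius_nm: float,
                          lattice_density_inv_nm: float = 1.625) -> float:
    """uM concentration of MT lattice binding sites in the nuclear volume."""
    volume_nm3 = 4.0 / 3.0 * np.pi * nucleus_radius_nm ** 3
    n_sites = total_mt_length_nm * lattice_density_inv_nm
    return n_sites / volume_nm3 * _UM_PER_MOLECULE_PER_NM3


def stage_one_binding_rate(association_per_um_site: float, k1_s: float,
                           total_mt_length_nm: float, nucleus_radius_nm: float,
                           n_free: int,
                           lattice_density_inv_nm: float = 1.625) -> float:
    """Aggregate solution -> one-head binding rate (s^-1).

    The on-rate per free molecule is Ka k1 [sites], with [sites] the molar
    concentration of lattice sites on all MTs in the nucleus; this is
    microscopically reversible against the zero-force off-rate k1, giving
    a Langmuir isotherm bound fraction Ka S / (1 + Ka S) at equilibrium.
    The aggregate rate is proportional to the unbound copy number and to
    the total MT length.
    """
    if n_free <= 0:
        return 0.0
    conc = site_concentration_um(total_mt_length_nm, nucleus_radius_nm,
                                 lattice_density_inv_nm)
    return association_per_um_site * k1_s * conc * n_free


def stage_two_weights(head_point: np.ndarray, mt_minus: np.ndarray,
                      mt_axis: np.ndarray, mt_length: float, spring: float,
                      rest_length: float, ds: float = 4.0,
                      kbt: float = KBT_PN_NM):
    """Boltzmann weights for second-head binding along a candidate MT.

    The filament is discretized into segments of size ``ds``; each segment
    carries weight exp(-U/kBT) with U the tether stretch energy to the
    segment midpoint.  The stage-two binding rate is
    c2 * k2 * ds * sum(weights) (times the antiparallel-affinity factor for
    crosslinkers), which makes the two-head chain microscopically
    reversible against the per-head off-rate k2.

    Returns ``(arc_positions, weights)``.
    """
    n_seg = max(1, int(mt_length / ds))
    s = (np.arange(n_seg) + 0.5) * (mt_length / n_seg)
    pts = mt_minus[None, :] + s[:, None] * mt_axis[None, :]
    d = np.linalg.norm(pts - head_point[None, :], axis=1)
    stretch = d - rest_length
    u = 0.5 * spring * stretch ** 2
    return s, np.exp(-u / kbt)
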