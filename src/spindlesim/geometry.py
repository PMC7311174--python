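"""Rigid-body geometry, steric forces, Brownian-dynamics stepping, and
nuclear-envelope confinement.

Bodies are spheres or spherocylinders (segments with a radius) in a
spherical nucleus of radius R.  The nuclear envelope is either rigid
(SPBs pinned to the sphere, hard wall for MT plus ends) or soft (radial
excursions against a saturating deformation force).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _formulas as f
from .params import KBT_PN_NM


@dataclass
class Spherocylinder:
    """A segment of given length and diameter (nm), centered at ``center``."""

    center: np.ndarray
    axis: np.ndarray
    length: float
    diameter: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.length < 0:
            raise ValueError("spherocylinder length must be >= 0")
        n = np.linalg.norm(self.axis)
        if n == 0 and self.length > 0:
            raise ValueError("zero axis for finite-length spherocylinder")
        self.axis = self.axis / n if n > 0 else np.array([0.0, 0.0, 1.0])

    @property
    def end_minus(self) -> np.ndarray:
        return self.center - 0.5 * self.length * self.axis

    @property
    def end_plus(self) -> np.ndarray:
        return self.center + 0.5 * self.length * self.axis


def min_distance_spherocylinders(a: Spherocylinder, b: Spherocylinder):
    """Minimum surface separation and closest axis points of two bodies.

    Returns ``(distance, point_a, point_b)``; distance is negative when the
    surfaces overlap.  Zero-length bodies degenerate to spheres.
    """
    _, _, d, pa, pb = f.closest_points_segments(
        a.end_minus, a.end_plus, b.end_minus, b.end_plus)
    return d - 0.5 * (a.diameter + b.diameter), pa, pb


def steric_force(distance: float, diameter_sum: float,
                 epsilon: float = KBT_PN_NM, force_clamp: float = 200.0) -> float:
    """Short-range hard-core repulsion magnitude (WCA form).

    ``distance`` is the surface separation from
    :func:`min_distance_spherocylinders`; ``diameter_sum`` the sum of the
    two diameters.  Zero at and beyond the cutoff, strictly increasing as
    the bodies interpenetrate, clamped for numerical stability.
    """
    sigma = 0.5 * diameter_sum
    return f.wca_force_mag(distance, sigma, epsilon, force_clamp)


def steric_energy(distance: float, diameter_sum: float,
                  epsilon: float = KBT_PN_NM) -> float:
    """Energy of the WCA steric interaction (zero at the cutoff)."""
    return f.wca_energy(distance, 0.5 * diameter_sum, epsilon)


def chromatin_mt_soft_repulsion(chromatin: Spherocylinder, mt: Spherocylinder,
                                amplitude: float = 1.0):
    """Soft overlap penalty between pericentric chromatin and an MT.

    Unlike the hard-core MT-MT interaction, the chromatin allows full
    overlap at finite energy cost: E = A (delta/sigma)^2, capped at A for
    a coaxial configuration.  Returns ``(energy, force_on_mt)`` with the
    force equal to minus the gradient of the energy with respect to the MT
    position, directed along the closest-point connector.
    """
    dist, pa, pb = min_distance_spherocylinders(chromatin, mt)
    sigma = 0.5 * (chromatin.diameter + mt.diameter)
    energy = f.chromatin_overlap_energy(dist, sigma, amplitude)
    mag = f.chromatin_overlap_force(dist, sigma, amplitude)
    if mag == 0.0:
        return energy, np.zeros(3)
    dv = pb - pa
    n = np.linalg.norm(dv)
    if n < 1e-9:
        # coaxial degenerate: energy is flat (capped); no force direction
        return energy, np.zeros(3)
    return energy, mag * dv / n


def bd_step(position: np.ndarray, force: np.ndarray, mobility, dt: float,
            rng: np.random.Generator, kbt: float = KBT_PN_NM,
            orientation: np.ndarray | None = None,
            torque: np.ndarray | None = None, mobility_rot: float = 0.0):
    """One Brownian-dynamics step for a point or rod-like body.

    Translation: x' = x + mu F dt + sqrt(2 D dt) N(0,1) per Cartesian degree
    of freedom with D = mu kBT (Einstein relation).  ``mobility`` is either
    a scalar (isotropic) or a ``(mu_parallel, mu_perp)`` pair applied in the
    frame of ``orientation``.  If an orientation and rotational mobility are
    given, the axis is rotated by mu_r T dt plus rotational diffusion about
    two axes perpendicular to itself and renormalized.

    Returns ``new_position`` or ``(new_position, new_orientation)``.
    """
    position = np.asarray(position, dtype=float)
    force = np.asarray(force, dtype=float)
    if np.isscalar(mobility):
        drift = mobility * force * dt
        noise = (np.sqrt(2.0 * mobility * kbt * dt) * rng.standard_normal(3)
                 if kbt > 0 else np.zeros(3))
        new_pos = position + drift + noise
    else:
        mu_par, mu_perp = mobility
        u = np.asarray(orientation, dtype=float)
        u = u / np.linalg.norm(u)
        f_par = np.dot(force, u) * u
        f_perp = force - f_par
        drift = (mu_par * f_par + mu_perp * f_perp) * dt
        if kbt > 0:
            g = rng.standard_normal(3)
            g_par = np.dot(g, u) * u
            g_perp = g - g_par
            noise = (np.sqrt(2.0 * mu_par * kbt * dt) * g_par
                     + np.sqrt(2.0 * mu_perp * kbt * dt) * g_perp)
        else:
            noise = np.zeros(3)
        new_pos = position + drift + noise
    if orientation is None:
        return new_pos
    u = np.asarray(orientation, dtype=float)
    u = u / np.linalg.norm(u)
    if mobility_rot > 0.0:
        t = np.zeros(3) if torque is None else np.asarray(torque, dtype=float)
        omega = mobility_rot * t * dt
        if kbt > 0:
            d_rot = mobility_rot * kbt
            omega = omega + np.sqrt(2.0 * d_rot * dt) * rng.standard_normal(3)
        # rotate u by the (small) rotation vector omega
        u = u + np.cross(omega, u)
        u = u / np.linalg.norm(u)
    return new_pos, u


def constrain_spb(position: np.ndarray, mode: str, radius: float,
                  spb_wall_force: float = 17.0, tube_radius: float = 87.7):
    """Apply the nuclear-envelope constraint to an SPB.

    Rigid mode projects the position back onto the sphere ``|x| = R`` and
    reports the radial constraint force as None (constraint, not a force).
    Soft mode leaves the position free and returns the radial
    envelope-deformation force: zero at the preferred radius, saturating
    at ``spb_wall_force`` for excursions large compared to the membrane
    tube radius, always restoring toward R.
    """
    position = np.asarray(position, dtype=float)
    r = np.linalg.norm(position)
    if r == 0.0:
        raise ValueError("SPB at nuclear center has no radial direction")
    rhat = position / r
    if mode == "rigid":
        return radius * rhat, np.zeros(3)
    excursion = abs(r - radius)
    mag = f.soft_wall_force(excursion, spb_wall_force, tube_radius)
    direction = -rhat if r > radius else rhat
    return position.copy(), mag * direction


def mt_confinement_force(plus_end: np.ndarray, radius: float, mode: str,
                         mt_wall_force: float = 2.5, tube_radius: float = 87.7,
                         wall_spring: float = 1.0):
    """Confinement force on an MT plus end from the nuclear envelope.

    Zero strictly inside the sphere.  Rigid mode: inward harmonic wall
    (numerical realization of a hard wall), normal to the envelope at the
    contact point.  Soft mode: inward force saturating at the tabulated
    asymptotic MT wall force.  The axial (along-MT) component of this force
    is what feeds the force-induced catastrophe model.
    """
    plus_end = np.asarray(plus_end, dtype=float)
    r = np.linalg.norm(plus_end)
    if r <= radius or r == 0.0:
        return np.zeros(3)
    rhat = plus_end / r
    excursion = r - radius
    if mode == "rigid":
        mag = wall_spring * excursion
    else:
        mag = f.soft_wall_force(excursion, mt_wall_force, tube_radius)
    return -mag * rhat


def mt_drag_coefficients(length: float, diameter: float = 25.0,
                         viscosity_pa_s: float = 1.0):
    """Translational (parallel, perpendicular) and rotational drags of a rod.

    Slender-body theory for a rigid rod of the given length/diameter in a
    medium of the given viscosity; units pN s / nm and pN nm s.  The
    corresponding diffusion coefficients follow from D = kBT / gamma.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    eta = viscosity_pa_s * 1.0e-6  # Pa s -> pN s / nm^2
    return f.mt_drag_coefficients(length, diameter, eta)
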