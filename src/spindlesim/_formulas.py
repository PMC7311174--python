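"""Low-level numerical kernels shared by the public API and the engine.

Everything here is a plain ``@njit`` function on scalars / small arrays so
the same compiled code backs both the user-facing operations and the hot
simulation loop.  Units: pN, nm, s; energies in pN nm.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_SIXTH = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# Geometry: segments and spherocylinders
# ---------------------------------------------------------------------------

@njit(cache=True)
def closest_points_segments(a0, a1, b0, b1):
    """Closest points between segments [a0,a1] and [b0,b1].

    Returns (s, t, dist, pa, pb) with s, t in [0, 1] the normalized arc
    parameters of the closest points pa, pb.  Robust for degenerate
    (zero-length) segments, which collapse to points.
    """
    d1 = a1 - a0
    d2 = b1 - b0
    r = a0 - b0
    A = d1[0] * d1[0] + d1[1] * d1[1] + d1[2] * d1[2]
    e = d2[0] * d2[0] + d2[1] * d2[1] + d2[2] * d2[2]
    f = d2[0] * r[0] + d2[1] * r[1] + d2[2] * r[2]
    EPS = 1e-12
    if A <= EPS and e <= EPS:
        s = 0.0
        t = 0.0
    elif A <= EPS:
        s = 0.0
        t = min(max(f / e, 0.0), 1.0)
    else:
        c = d1[0] * r[0] + d1[1] * r[1] + d1[2] * r[2]
        if e <= EPS:
            t = 0.0
            s = min(max(-c / A, 0.0), 1.0)
        else:
            bb = d1[0] * d2[0] + d1[1] * d2[1] + d1[2] * d2[2]
            denom = A * e - bb * bb
            if denom > EPS:
                s = min(max((bb * f - c * e) / denom, 0.0), 1.0)
            else:
                s = 0.0
            t = (bb * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(max(-c / A, 0.0), 1.0)
            elif t > 1.0:
                t = 1.0
                s = min(max((bb - c) / A, 0.0), 1.0)
    pa = a0 + s * d1
    pb = b0 + t * d2
    dv = pa - pb
    dist = np.sqrt(dv[0] * dv[0] + dv[1] * dv[1] + dv[2] * dv[2])
    return s, t, dist, pa, pb


@njit(cache=True)
def closest_point_segment(p, a0, a1):
    """Closest point on segment [a0,a1] to point p: returns (t, dist, q)."""
    d = a1 - a0
    dd = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
    if dd <= 1e-12:
        t = 0.0
    else:
        t = ((p[0] - a0[0]) * d[0] + (p[1] - a0[1]) * d[1]
             + (p[2] - a0[2]) * d[2]) / dd
        t = min(max(t, 0.0), 1.0)
    q = a0 + t * d
    dv = p - q
    dist = np.sqrt(dv[0] * dv[0] + dv[1] * dv[1] + dv[2] * dv[2])
    return t, dist, q


# ---------------------------------------------------------------------------
# Steric and confinement forces
# ---------------------------------------------------------------------------

@njit(cache=True)
def wca_force_mag(surface_dist, sigma, eps, f_clamp):
    """WCA repulsion magnitude from the surface separation of two bodies.

    ``sigma`` is the sum of radii (contact at surface_dist = 0, i.e.
    centerline distance r = sigma); force is zero beyond the cutoff
    r = 2^(1/6) sigma and clamped at ``f_clamp`` for deep overlap.
    """
    r = surface_dist + sigma
    if r >= TWO_SIXTH * sigma:
        return 0.0
    if r < 0.05 * sigma:
        r = 0.05 * sigma
    sr2 = (sigma / r) * (sigma / r)
    sr6 = sr2 * sr2 * sr2
    f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    if f > f_clamp:
        f = f_clamp
    if f < 0.0:
        f = 0.0
    return f


@njit(cache=True)
def wca_energy(surface_dist, sigma, eps):
    """WCA energy (shifted so it vanishes at the cutoff)."""
    r = surface_dist + sigma
    if r >= TWO_SIXTH * sigma:
        return 0.0
    if r < 0.05 * sigma:
        r = 0.05 * sigma
    sr2 = (sigma / r) * (sigma / r)
    sr6 = sr2 * sr2 * sr2
    return 4.0 * eps * (sr6 * sr6 - sr6) + eps


@njit(cache=True)
def soft_wall_force(excursion, f_wall, ftube):
    """Saturating envelope-deformation force magnitude.

    Zero at the preferred radius, asymptotically ``f_wall`` for excursions
    large compared to the membrane tube radius.
    """
    if excursion <= 0.0:
        return 0.0
    return f_wall * np.tanh(excursion / ftube)


@njit(cache=True)
def chromatin_overlap_energy(surface_dist, sigma, amplitude):
    """Soft quadratic overlap penalty between chromatin and an MT.

    Finite for full overlap: E = A (delta/sigma)^2 with delta the overlap
    depth, so E(max) = A at coaxial contact (delta = sigma).
    """
    if surface_dist >= 0.0:
        return 0.0
    delta = -surface_dist
    if delta > sigma:
        delta = sigma
    x = delta / sigma
    return amplitude * x * x


@njit(cache=True)
def chromatin_overlap_force(surface_dist, sigma, amplitude):
    """Repulsive force magnitude, -dE/d(distance), for the soft overlap."""
    if surface_dist >= 0.0:
        return 0.0
    delta = -surface_dist
    if delta > sigma:
        return 0.0
    return 2.0 * amplitude * delta / (sigma * sigma)


# ---------------------------------------------------------------------------
# Binding kinetics and motor mechanics
# ---------------------------------------------------------------------------

@njit(cache=True)
def bell_rate(k0, force, xc, kbt):
    """Force-dependent (un)binding rate k0 * exp(F xc / kBT).

    ``force`` is the scalar tether tension (>= 0); negative ``xc`` yields
    catch-bond (force-stabilized) behavior.
    """
    if force < 0.0:
        force = 0.0
    return k0 * np.exp(force * xc / kbt)


@njit(cache=True)
def force_velocity(v0, parallel_force, fs):
    """Linear force-velocity relation v0 (1 - f/Fs).

    ``parallel_force`` is the load component opposing motion (positive =
    opposing).  The (1 - f/Fs) factor is clamped to [0, 2] so assisting
    loads at most double the speed and super-stall loads stall the head.
    """
    x = 1.0 - parallel_force / fs
    if x < 0.0:
        x = 0.0
    elif x > 2.0:
        x = 2.0
    return v0 * x


@njit(cache=True)
def binding_weight(energy, kbt):
    """Boltzmann weight exp(-U/kBT) of a stretched tether."""
    return np.exp(-energy / kbt)


@njit(cache=True)
def spring_energy(k, stretch):
    return 0.5 * k * stretch * stretch


@njit(cache=True)
def kmc_prob(rate, dt):
    """Probability that a Poisson event with rate k fires within dt."""
    return 1.0 - np.exp(-rate * dt)


# ---------------------------------------------------------------------------
# Microtubule dynamic instability
# ---------------------------------------------------------------------------

@njit(cache=True)
def effective_di_params(vg, vs, fc, fr, stabilized, svg, svs, sfc, sfr,
                        attached, tip_force, f_vg, f_vs, f_fc, f_fr, v_max):
    """Apply crosslink stabilization and end-on attachment force factors.

    ``tip_force`` is the tension along the MT axis at the plus end (positive
    pulling outward).  Both modifications compose multiplicatively; growth
    speed is capped at v_max after all factors.
    """
    if stabilized:
        vg *= svg
        vs *= svs
        fc *= sfc
        fr *= sfr
    if attached:
        vg *= np.exp(tip_force / f_vg)
        vs *= np.exp(tip_force / f_vs)
        fc *= np.exp(tip_force / f_fc)
        fr *= np.exp(tip_force / f_fr)
    if vg > v_max:
        vg = v_max
    return vg, vs, fc, fr


@njit(cache=True)
def catastrophe_rate(fc_eff, compressive_force, alpha_c):
    """Force-induced catastrophe: fc_eff * exp(alpha_c * F), F >= 0."""
    if compressive_force < 0.0:
        compressive_force = 0.0
    return fc_eff * np.exp(alpha_c * compressive_force)


# ---------------------------------------------------------------------------
# Drag coefficients
# ---------------------------------------------------------------------------

@njit(cache=True)
def mt_drag_coefficients(length, diameter, eta):
    """Slender-body rigid-rod drags (parallel, perpendicular, rotational).

    Log corrections are clamped for stubby rods so drags stay positive and
    monotone in length down to the minimum MT length.
    """
    lam = np.log(length / diameter)
    if lam < 0.5:
        lam = 0.5
    g_par = 2.0 * np.pi * eta * length / lam
    g_perp = 2.0 * g_par
    g_rot = np.pi * eta * length ** 3 / (3.0 * lam)
    return g_par, g_perp, g_rot


# ---------------------------------------------------------------------------
# Small vector helpers
# ---------------------------------------------------------------------------

@njit(cache=True)
def normalize(v):
    n = np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if n < 1e-300:
        out = np.zeros(3)
        out[2] = 1.0
        return out
    return v / n


@njit(cache=True)
def cross(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


@njit(cache=True)
def dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


@njit(cache=True)
def rotate_about(v, axis, angle):
    """Rodrigues rotation of v about unit axis."""
    c = np.cos(angle)
    s = np.sin(angle)
    k = axis
    kv = cross(k, v)
    kdv = dot(k, v)
    return v * c + kv * s + k * (kdv * (1.0 - c))
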