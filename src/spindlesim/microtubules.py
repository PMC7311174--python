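"""Microtubule plus-end dynamic instability.

MTs are rigid spherocylinders whose minus ends are tethered to an SPB
nucleation site by a spring; the plus end stochastically switches between
growth and shrinkage (catastrophe / rescue).  Compressive load at the tip
promotes catastrophe; crosslink-mediated stabilization and force-dependent
end-on kinetochore attachment rescale all four dynamic-instability
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _formulas as f
from .params import UM_MIN_TO_NM_S, MTParams

GROWING = 1
SHRINKING = 0


@dataclass
class DynamicInstabilityParams:
    """Four-parameter DI set in internal units (nm/s, s^-1)."""

    vg: float
    vs: float
    fc: float
    fr: float

    @classmethod
    def from_table(cls, mt: MTParams | None = None) -> "DynamicInstabilityParams":
        mt = mt or MTParams()
        return cls(vg=mt.growth_speed_um_min * UM_MIN_TO_NM_S,
                   vs=mt.shrink_speed_um_min * UM_MIN_TO_NM_S,
                   fc=mt.catastrophe_freq_per_min / 60.0,
                   fr=mt.rescue_freq_per_min / 60.0)


def effective_di_params(base: DynamicInstabilityParams, stabilized: bool = False,
                        tip_force: float | None = None,
                        mt: MTParams | None = None,
                        f_vg: float = 8.4, f_vs: float = -3.0,
                        f_fc: float = -2.3, f_fr: float = 6.4,
                        v_max_nm_s: float = 500.0) -> DynamicInstabilityParams:
    """Stabilization multipliers and end-on attachment force factors.

    ``tip_force`` (pN, tension positive) is the axial load at the tip of an
    end-on attached MT; ``None`` means unattached.  Both effects compose
    multiplicatively and the growth speed is capped at ``v_max_nm_s``.
    """
    mt = mt or MTParams()
    attached = tip_force is not None
    vg, vs, fc, fr = f.effective_di_params(
        base.vg, base.vs, base.fc, base.fr,
        stabilized, mt.stab_growth, mt.stab_shrink, mt.stab_catastrophe,
        mt.stab_rescue, attached, tip_force if attached else 0.0,
        f_vg, f_vs, f_fc, f_fr, v_max_nm_s)
    return DynamicInstabilityParams(vg, vs, fc, fr)


def catastrophe_rate(fc_eff: float, compressive_force: float,
                     alpha_c: float = 0.5) -> float:
    """Catastrophe rate under compressive axial tip load: fc exp(alpha_c F)."""
    return f.catastrophe_rate(fc_eff, compressive_force, alpha_c)


def stationary_mean_length(p: DynamicInstabilityParams) -> float:
    """Mean length of the bounded-growth stationary (exponential) regime.

    <L> = vg vs / (vs fc - vg fr); requires vs fc > vg fr, else the
    population grows without bound and there is no stationary state.
    """
    denom = p.vs * p.fc - p.vg * p.fr
    if denom <= 0:
        raise ValueError("unbounded growth: vs*fc must exceed vg*fr")
    return p.vg * p.vs / denom


def di_update(lengths: np.ndarray, states: np.ndarray,
              p: DynamicInstabilityParams, dt: float,
              rng: np.random.Generator, l_min: float = 75.0):
    """One kMC timestep of dynamic instability for an ensemble of MTs.

    Growing MTs elongate by vg dt and catastrophe with probability
    1 - exp(-fc dt); shrinking MTs shorten by vs dt and rescue with
    probability 1 - exp(-fr dt).  An MT reaching the minimum length is
    clamped there and set growing (nucleation-site refresh).  Arrays are
    updated in place and returned.
    """
    lengths = np.asarray(lengths, dtype=float)
    states = np.asarray(states)
    grow = states == GROWING
    lengths[grow] += p.vg * dt
    lengths[~grow] -= p.vs * dt
    u = rng.random(lengths.shape)
    cat = grow & (u < 1.0 - np.exp(-p.fc * dt))
    res = (~grow) & (u < 1.0 - np.exp(-p.fr * dt))
    states[cat] = SHRINKING
    states[res] = GROWING
    short = lengths <= l_min
    lengths[short] = l_min
    states[short] = GROWING
    return lengths, states


def sample_stationary_lengths(p: DynamicInstabilityParams, n_mt: int,
                              t_total_s: float, dt: float,
                              seed: int = 0, l_min: float = 75.0,
                              snapshot_every_s: float | None = None):
    """Simulate an unloaded ensemble and return sampled lengths (nm).

    Returns the final snapshot, or — with ``snapshot_every_s`` — the
    concatenation of snapshots taken over the second half of the run
    (burn-in discarded), which averages over the length autocorrelation
    time for a lower-variance mean estimate.
    """
    rng = np.random.default_rng(seed)
    lengths = np.full(n_mt, l_min)
    states = np.full(n_mt, GROWING, dtype=np.int64)
    n_steps = int(t_total_s / dt)
    snaps = []
    snap_stride = (int(snapshot_every_s / dt) if snapshot_every_s else None)
    for step in range(n_steps):
        di_update(lengths, states, p, dt, rng, l_min)
        if snap_stride and step > n_steps // 2 and step % snap_stride == 0:
            snaps.append(lengths.copy())
    if snaps:
        return np.concatenate(snaps)
    return lengths


def nucleate_mts(spb_position: np.ndarray, spb_normal: np.ndarray,
                 rng: np.random.Generator, n_mts: int = 14,
                 spb_diameter: float = 162.5, l_min: float = 75.0,
                 mt_diameter: float = 25.0):
    """Nucleate the SPB's MTs at minimum length, growing, pointing inward.

    Minus ends sit at distinct anchor sites scattered on the SPB face;
    axes are drawn uniformly over the inward-facing hemisphere (broad
    splay).  Returns ``(minus_ends, axes, lengths, states)``.
    """
    spb_position = np.asarray(spb_position, dtype=float)
    n = np.asarray(spb_normal, dtype=float)
    n = n / np.linalg.norm(n)
    # orthonormal tangent frame on the SPB face
    t1 = np.cross(n, [0.0, 0.0, 1.0])
    if np.linalg.norm(t1) < 1e-6:
        t1 = np.cross(n, [0.0, 1.0, 0.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    r_face = 0.45 * spb_diameter
    minus = np.empty((n_mts, 3))
    axes = np.empty((n_mts, 3))
    for i in range(n_mts):
        rho = r_face * np.sqrt(rng.random())
        phi = 2.0 * np.pi * rng.random()
        minus[i] = spb_position + rho * (np.cos(phi) * t1 + np.sin(phi) * t2)
        while True:
            a = rng.standard_normal(3)
            a /= np.linalg.norm(a)
            if np.dot(a, n) > 0.05:
                break
        axes[i] = a
    lengths = np.full(n_mts, l_min)
    states = np.full(n_mts, GROWING, dtype=np.int64)
    return minus, axes, lengths, states
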