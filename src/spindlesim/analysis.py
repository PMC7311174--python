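"""Observables and figure-level statistics computed from trajectories.

The headline metrics of the model: fraction of time with all chromosomes
simultaneously bioriented, spindle length fluctuation magnitude,
kinetochore-MT attachment lifetime, the axial (spindle-axis) force
decomposition by molecular class, and simulated fluorescence rendering.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import engine
from .driver import SimulationState, Trajectory
from .params import ModelParams

CLASS_NAMES = ("kinesin5", "kinesin14", "crosslinker", "chromosome")


def fraction_simultaneous_biorientation(traj: Trajectory) -> float:
    """Time-weighted fraction of samples with every chromosome amphitelic."""
    if traj.chromosome_states.shape[0] == 0:
        return 0.0
    return float(np.mean(traj.all_bioriented()))


def length_fluctuation_magnitude(trajectories, onset_min: float = 10.0) -> float:
    """Mean over runs of the per-run spindle-length standard deviation (um).

    Only samples after the bipolar-spindle onset time contribute; runs
    shorter than the onset are excluded with a warning.
    """
    stds = []
    for traj in trajectories:
        t_min = traj.times_min
        mask = t_min > onset_min
        if mask.sum() < 2:
            warnings.warn("run shorter than the fluctuation onset; excluded")
            continue
        stds.append(float(np.std(traj.spindle_length_um[mask])))
    if not stds:
        raise ValueError("no run long enough for the fluctuation onset")
    return float(np.mean(stds))


def attachment_lifetime(traj: Trajectory) -> float:
    """Mean kinetochore-MT attachment lifetime (min).

    An attachment is a contiguous interval during which one attachment
    factor stays bound to the same MT; a lateral/end-on mode change on the
    same MT is one continuous attachment.  Right-censored intervals (still
    bound at the end of the trajectory) are excluded.  Returns NaN and
    warns if no completed interval exists.
    """
    intervals = attachment_intervals(traj)
    if intervals.size == 0:
        warnings.warn("no completed attachment interval in trajectory")
        return float("nan")
    return float(np.mean(intervals)) / 60.0


def attachment_intervals(traj: Trajectory) -> np.ndarray:
    """Completed attachment durations (s) for all attachment factors."""
    times = traj.times_s
    if times.size < 2:
        return np.array([])
    out = []
    naf = traj.af_mt.shape[1]
    for i in range(naf):
        bound_mt = traj.af_mt[:, i]
        start = None
        current = -1
        for s in range(times.size):
            m = bound_mt[s]
            if m >= 0 and m == current:
                continue
            if start is not None:
                out.append(times[s] - times[start])
                start = None
                current = -1
            if m >= 0:
                start = s
                current = m
        # interval still open at the end: right-censored, excluded
    return np.asarray(out)


def axial_force_decomposition(state: SimulationState, params: ModelParams) -> dict:
    """Per-class axial force (pN) transmitted between the half-spindles.

    For each class (kinesin-5, kinesin-14, crosslinker, chromosome), the
    spindle-axis components of the spring forces the class exerts on each
    half-spindle's MTs are summed; the reported value is the mean of the
    two half-spindle outward components, so mirror-symmetric states give
    equal weight to both halves.  Positive = outward (pole-separating).
    Only linkers bridging the two halves and kinetochore-MT attachment
    tethers transmit force between the halves.
    """
    axis = state.spb_pos[1] - state.spb_pos[0]
    n = np.linalg.norm(axis)
    axis = axis / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])
    out = {name: 0.0 for name in CLASS_NAMES}

    spring = {engine.SP_K5: (params.kinesin5.spring_pn_nm,
                             params.kinesin5.rest_length_nm),
              engine.SP_K14: (params.kinesin14.spring_pn_nm,
                              params.kinesin14.rest_length_nm),
              engine.SP_XL: (params.crosslinker.spring_pn_nm,
                             params.crosslinker.rest_length_nm)}

    def head_point(j, arc):
        return state.mt_center[j] + (arc - 0.5 * state.mt_len[j]) * state.mt_axis[j]

    for il in range(state.lk_sp.shape[0]):
        if state.lk_state[il] != engine.LK_BOTH:
            continue
        i0, i1 = state.lk_mt[il]
        if state.mt_spb[i0] == state.mt_spb[i1]:
            continue
        K, r0 = spring[state.lk_sp[il]]
        h0 = head_point(i0, state.lk_pos[il, 0])
        h1 = head_point(i1, state.lk_pos[il, 1])
        dv = h1 - h0
        d = np.linalg.norm(dv)
        if d < 1e-9:
            continue
        f0 = K * (d - r0) * dv / d   # force on head 0's MT
        s0 = 1.0 if state.mt_spb[i0] == 1 else -1.0
        s1 = 1.0 if state.mt_spb[i1] == 1 else -1.0
        name = CLASS_NAMES[state.lk_sp[il]]
        out[name] += 0.5 * (s0 * np.dot(f0, axis) + s1 * np.dot(-f0, axis))

    ka = params.attachment
    for i in range(state.af_mode.shape[0]):
        if state.af_mode[i] == engine.AF_UNBOUND:
            continue
        k = i // 3
        slot = i % 3
        site = (state.kc_pos[k]
                + (slot - 1) * params.chromosome.site_spacing_nm * state.kc_t[k])
        j = state.af_mt[i]
        h = head_point(j, min(state.af_pos[i], state.mt_len[j]))
        dv = site - h
        d = np.linalg.norm(dv)
        if d < 1e-9:
            continue
        f_mt = ka.spring_pn_nm * (d - ka.rest_length_nm) * dv / d
        sgn = 1.0 if state.mt_spb[j] == 1 else -1.0
        out["chromosome"] += 0.5 * sgn * np.dot(f_mt, axis)
    return out


def render_fluorescence(state: SimulationState, params: ModelParams,
                        channels=("mt", "kc"), psf_width_nm: float = 150.0,
                        pixel_nm: float = 40.0, half_size_nm: float = 2000.0,
                        kc_index: int = 0) -> dict:
    """Simulated fluorescence images, one 2D array per channel.

    Maximum-intensity-style projection of Gaussian-convolved line density
    (MTs) and spots (one kinetochore pair), with the state rotated so the
    spindle axis is vertical in the image.
    """
    from scipy.ndimage import gaussian_filter

    axis = state.spb_pos[1] - state.spb_pos[0]
    n = np.linalg.norm(axis)
    ey = axis / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, ey)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    ex = np.cross(ey, ref)
    ex /= np.linalg.norm(ex)
    origin = 0.5 * (state.spb_pos[0] + state.spb_pos[1])

    npix = int(2 * half_size_nm / pixel_nm)
    sigma_pix = psf_width_nm / pixel_nm

    def splat(points, weights, img):
        for p, w in zip(points, weights):
            d = p - origin
            x = np.dot(d, ex) + half_size_nm
            y = np.dot(d, ey) + half_size_nm
            ix = int(x / pixel_nm)
            iy = int(y / pixel_nm)
            if 0 <= ix < npix and 0 <= iy < npix:
                img[iy, ix] += w

    images = {}
    if "mt" in channels:
        img = np.zeros((npix, npix))
        ds = 20.0
        for j in range(state.n_mts):
            L = state.mt_len[j]
            nseg = max(1, int(L / ds))
            s = (np.arange(nseg) + 0.5) * (L / nseg)
            minus = state.mt_center[j] - 0.5 * L * state.mt_axis[j]
            pts = minus[None, :] + s[:, None] * state.mt_axis[j][None, :]
            splat(pts, np.full(nseg, L / nseg), img)
        images["mt"] = gaussian_filter(img, sigma_pix)
    if "kc" in channels:
        img = np.zeros((npix, npix))
        pair = state.kc_pos[2 * kc_index:2 * kc_index + 2]
        if pair.shape[0]:
            splat(pair, np.full(pair.shape[0], 100.0), img)
        images["kc"] = gaussian_filter(img, sigma_pix)
    return images


def summary_stats(trajectories, onset_min: float = 10.0) -> dict:
    """Headline summary of one or more runs of the same model."""
    trajs = list(trajectories)
    frac = float(np.mean([fraction_simultaneous_biorientation(t) for t in trajs]))
    lifetimes = [attachment_lifetime(t) for t in trajs]
    lifetimes = [x for x in lifetimes if np.isfinite(x)]
    stretch = float(np.mean([np.mean(t.interkc_nm) for t in trajs])) / 1000.0
    try:
        fluct = length_fluctuation_magnitude(trajs, onset_min)
    except ValueError:
        fluct = float("nan")
    return {
        "fraction_simultaneous_biorientation": frac,
        "mean_attachment_lifetime_min":
            float(np.mean(lifetimes)) if lifetimes else float("nan"),
        "length_fluctuation_magnitude_um": fluct,
        "mean_interkinetochore_distance_um": stretch,
    }
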