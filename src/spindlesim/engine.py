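"""Compiled simulation core.

One numba kernel advances the whole system: force/torque accumulation
(tethers, sterics, confinement, motor/crosslinker springs, attachment
tethers and angular springs, interkinetochore springs, soft chromatin),
Brownian-dynamics updates of SPBs, MTs, and kinetochore plates, plus-end
dynamic instability, and kinetic Monte Carlo sampling of every binding /
unbinding / context-switch event.  All state lives in flat numpy arrays;
the parameter vector ``P`` is indexed by the ``IP_*`` constants generated
from :data:`spindlesim.params.PARAM_INDEX`.

Integration order per step (operator splitting at dt much smaller than
every kinetic timescale): forces -> BD updates -> constraint projection ->
dynamic instability -> kMC state changes.  Two numerical cadences keep the
cost tractable without touching the physics: binding/unbinding and bound-
head motion of motors and crosslinkers run every ``kinetics_stride`` steps
with the correspondingly larger kMC timestep (still far below every
kinetic and mechanical relaxation time), and the geometry-dependent
association rates (neighbor sums) are refreshed every
``binding_refresh_steps`` steps, with event targets re-enumerated exactly
when an event fires.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import PARAM_INDEX

# parameter slots as module-level (compile-time) constants
for _name, _i in PARAM_INDEX.items():
    globals()["IP_" + _name.upper()] = _i

# species ids
SP_K5 = 0
SP_K14 = 1
SP_XL = 2

# linker stages
LK_FREE = 0
LK_HEAD0 = 1   # only head 0 bound (motor head for kinesin-14)
LK_HEAD1 = 2   # only head 1 bound (passive head for kinesin-14)
LK_BOTH = 3

# attachment modes
AF_UNBOUND = 0
AF_LATERAL = 1
AF_ENDON = 2

# chromosome states
CS_LOST = 0
CS_MONOTELIC = 1
CS_SYNTELIC = 2
CS_AMPHITELIC = 3
CS_MEROTELIC = 4

STATUS_OK = 0
STATUS_NAN = 3

_UM_PER_NM3 = 1.0e30 / 6.02214076e23  # uM per (molecule / nm^3)


@njit(cache=True, inline="always")
def _next64(rs):
    """xorshift128+ step on the 2-word uint64 state; returns a uint64."""
    s1 = rs[0]
    s0 = rs[1]
    rs[0] = s0
    s1 = s1 ^ (s1 << np.uint64(23))
    s1 = s1 ^ s0 ^ (s1 >> np.uint64(18)) ^ (s0 >> np.uint64(5))
    rs[1] = s1
    return s1 + s0


@njit(cache=True, inline="always")
def _u01(rs):
    """Uniform double in [0, 1) from the top 53 bits."""
    return float(_next64(rs) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _randn(rs, gsp):
    """Standard normal (Marsaglia polar, spare cached in gsp[0:2])."""
    if gsp[0] > 0.5:
        gsp[0] = 0.0
        return gsp[1]
    while True:
        v1 = 2.0 * _u01(rs) - 1.0
        v2 = 2.0 * _u01(rs) - 1.0
        s = v1 * v1 + v2 * v2
        if 0.0 < s < 1.0:
            break
    fac = np.sqrt(-2.0 * np.log(s) / s)
    gsp[0] = 1.0
    gsp[1] = v2 * fac
    return v1 * fac


@njit(cache=True)
def _binom(rs, n, p):
    """Binomial sample by CDF inversion (efficient for small n*p)."""
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    q = (1.0 - p) ** n
    u = _u01(rs)
    k = 0
    c = q
    ratio = p / (1.0 - p)
    while u > c and k < n:
        q = q * float(n - k) / float(k + 1) * ratio
        k += 1
        c += q
    return k


@njit(cache=True)
def _seed_state(seed, rs):
    """splitmix64 expansion of the integer seed into the xorshift state."""
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        t = z
        t = (t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        rs[i] = t ^ (t >> np.uint64(31))
        z += np.uint64(0x9E3779B97F4A7C15)
    if rs[0] == np.uint64(0) and rs[1] == np.uint64(0):
        rs[0] = np.uint64(0xDEADBEEF)


@njit(cache=True, fastmath=True, inline="always")
def _cexp(x):
    """exp with a clamped argument (avoids overflow in Bell factors)."""
    if x > 50.0:
        x = 50.0
    return np.exp(x)


@njit(cache=True, fastmath=True, inline="always")
def _pevent(rate, dt):
    """1 - exp(-rate dt), linearized where exact evaluation is wasteful."""
    x = rate * dt
    if x < 1e-4:
        return x
    return 1.0 - np.exp(-x)


@njit(cache=True, fastmath=True, inline="always")
def _nrm3(x, y, z):
    return np.sqrt(x * x + y * y + z * z)


@njit(cache=True, fastmath=True)
def _segseg(p1x, p1y, p1z, u1x, u1y, u1z, L1,
            p2x, p2y, p2z, u2x, u2y, u2z, L2):
    """Closest points of two segments given by minus end + unit axis + length.

    Returns (s, t, dist, pax, pay, paz, pbx, pby, pbz) with s in [0, L1],
    t in [0, L2] the arc positions of the closest points.
    """
    d1x, d1y, d1z = u1x * L1, u1y * L1, u1z * L1
    d2x, d2y, d2z = u2x * L2, u2y * L2, u2z * L2
    rx, ry, rz = p1x - p2x, p1y - p2y, p1z - p2z
    A = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    EPS = 1e-12
    if A <= EPS and e <= EPS:
        s = 0.0
        t = 0.0
    elif A <= EPS:
        s = 0.0
        t = f / e
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    else:
        c = d1x * rx + d1y * ry + d1z * rz
        if e <= EPS:
            t = 0.0
            s = -c / A
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
        else:
            b = d1x * d2x + d1y * d2y + d1z * d2z
            den = A * e - b * b
            if den > EPS:
                s = (b * f - c * e) / den
                if s < 0.0:
                    s = 0.0
                elif s > 1.0:
                    s = 1.0
            else:
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = -c / A
                if s < 0.0:
                    s = 0.0
                elif s > 1.0:
                    s = 1.0
            elif t > 1.0:
                t = 1.0
                s = (b - c) / A
                if s < 0.0:
                    s = 0.0
                elif s > 1.0:
                    s = 1.0
    pax = p1x + s * d1x
    pay = p1y + s * d1y
    paz = p1z + s * d1z
    pbx = p2x + t * d2x
    pby = p2y + t * d2y
    pbz = p2z + t * d2z
    dist = _nrm3(pax - pbx, pay - pby, paz - pbz)
    return s * L1, t * L2, dist, pax, pay, paz, pbx, pby, pbz


@njit(cache=True, fastmath=True, inline="always")
def _ptseg(px, py, pz, mx, my, mz, ux, uy, uz, L):
    """Closest point on a segment to a point: (arc, dist, qx, qy, qz)."""
    t = (px - mx) * ux + (py - my) * uy + (pz - mz) * uz
    if t < 0.0:
        t = 0.0
    elif t > L:
        t = L
    qx = mx + t * ux
    qy = my + t * uy
    qz = mz + t * uz
    return t, _nrm3(px - qx, py - qy, pz - qz), qx, qy, qz


@njit(cache=True, fastmath=True, inline="always")
def _wca(surface_dist, sigma, eps, f_clamp):
    r = surface_dist + sigma
    if r >= 1.1224620483093730 * sigma:
        return 0.0
    if r < 0.05 * sigma:
        r = 0.05 * sigma
    sr2 = (sigma / r) * (sigma / r)
    sr6 = sr2 * sr2 * sr2
    fm = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    if fm > f_clamp:
        fm = f_clamp
    elif fm < 0.0:
        fm = 0.0
    return fm


@njit(cache=True, fastmath=True)
def _classify(mask_a, mask_b):
    """Chromosome state from per-sister pole bitmasks (bit0 = SPB0, bit1 = SPB1)."""
    if mask_a == 0 and mask_b == 0:
        return CS_LOST
    if mask_a == 3 or mask_b == 3:
        return CS_MEROTELIC
    if mask_a == 0 or mask_b == 0:
        return CS_MONOTELIC
    if mask_a != mask_b:
        return CS_AMPHITELIC
    return CS_SYNTELIC


@njit(cache=True, fastmath=True)
def _af_bind_enumerate(P, sx, sy, sz, nx, ny, nz, occupancy,
                       mt_center, mt_axis, mt_len, mt_state, mt_tip_af,
                       choose, rpick):
    """Total attachment rate for one unbound attachment factor.

    Integrates the rate density c*k*exp(-U/kBT)*exp(-kappa theta^2/2kBT)
    over lateral segments within the Boltzmann-relevant window of every
    MT, plus the free-tip end-on candidates.  With ``choose`` set, picks
    the candidate at cumulative weight ``rpick``; returns
    (total, mt, mode, arc_pos).
    """
    kbt = P[IP_KBT]
    r0 = P[IP_AF_R0]
    km = P[IP_AF_KM]
    ds = P[IP_DS_SEG]
    tip_len = P[IP_TIP_LEN]
    wcut = r0 + 4.0 * np.sqrt(kbt / km) + ds
    if occupancy == 0:
        kappa = P[IP_AF_KR0]
    elif occupancy == 1:
        kappa = P[IP_AF_KR1]
    elif occupancy == 2:
        kappa = P[IP_AF_KR2]
    else:
        kappa = P[IP_AF_KR3]
    total = 0.0
    M = mt_center.shape[0]
    for j in range(M):
        L = mt_len[j]
        ux, uy, uz = mt_axis[j, 0], mt_axis[j, 1], mt_axis[j, 2]
        mx = mt_center[j, 0] - 0.5 * L * ux
        my = mt_center[j, 1] - 0.5 * L * uy
        mz = mt_center[j, 2] - 0.5 * L * uz
        px, py, pz = sx - mx, sy - my, sz - mz
        tinf = px * ux + py * uy + pz * uz
        dperp2 = px * px + py * py + pz * pz - tinf * tinf
        w2 = wcut * wcut - dperp2
        tipx = mx + L * ux
        tipy = my + L * uy
        tipz = mz + L * uz
        dtip = _nrm3(sx - tipx, sy - tipy, sz - tipz)
        if w2 <= 0.0 and dtip > wcut:
            continue
        cu = -(ux * nx + uy * ny + uz * nz)
        if cu > 1.0:
            cu = 1.0
        elif cu < -1.0:
            cu = -1.0
        theta = np.arccos(cu)
        ang_w = _cexp(-kappa * theta * theta / (2.0 * kbt))
        if ang_w > 1e-12 and w2 > 0.0:
            W = np.sqrt(w2)
            smin = tinf - W
            if smin < 0.0:
                smin = 0.0
            smax = tinf + W
            if smax > L:
                smax = L
            if smax > smin:
                nseg = int((smax - smin) / ds) + 1
                dseg = (smax - smin) / nseg
                pref = P[IP_C_SIDE] * P[IP_K_SIDE] * dseg * ang_w
                for k in range(nseg):
                    s = smin + (k + 0.5) * dseg
                    dd = _nrm3(sx - (mx + s * ux), sy - (my + s * uy),
                               sz - (mz + s * uz))
                    stretch = dd - r0
                    total += pref * _cexp(-0.5 * km * stretch * stretch / kbt)
                    if choose and total >= rpick:
                        return total, j, AF_LATERAL, s
        # end-on candidate: free tip within reach
        if mt_tip_af[j] < 0 and dtip <= wcut and ang_w > 1e-12:
            stretch = dtip - r0
            w = _cexp(-0.5 * km * stretch * stretch / kbt)
            kmode = P[IP_K_TIP_A] if mt_state[j] == 1 else P[IP_K_TIP_D]
            total += P[IP_C_TIP] * kmode * tip_len * w * ang_w
            if choose and total >= rpick:
                return total, j, AF_ENDON, L
    return total, -1, 0, 0.0


@njit(cache=True, fastmath=True)
def _lk_stage2_enumerate(P, sp, bound_head, imt, arc, mt_center, mt_axis,
                         mt_len, choose, rpick):
    """Second-head binding rate for a singly bound motor/crosslinker.

    rate = c2 * k2(other head) * ds * exp(-U/kBT) per candidate segment of
    every *other* MT (antiparallel-affinity factor applied for parallel
    crosslinker pairs), integrated over the Boltzmann-relevant window.
    """
    kbt = P[IP_KBT]
    ds = P[IP_DS_SEG]
    if sp == SP_K5:
        K = P[IP_K5_K]
        r0 = P[IP_K5_R0]
        c2 = P[IP_K5_C2]
        k2o = P[IP_K5_K2]
    elif sp == SP_K14:
        K = P[IP_K14_K]
        r0 = P[IP_K14_R0]
        if bound_head == 0:
            c2 = P[IP_K14_C2D]   # binding the passive head
            k2o = P[IP_K14_K2D]
        else:
            c2 = P[IP_K14_C2M]   # binding the motor head
            k2o = P[IP_K14_K2M]
    else:
        K = P[IP_XL_K]
        r0 = P[IP_XL_R0]
        c2 = P[IP_XL_C2]
        k2o = P[IP_XL_K2]
    wcut = r0 + 4.0 * np.sqrt(kbt / K) + ds
    Li = mt_len[imt]
    hx = mt_center[imt, 0] + (arc - 0.5 * Li) * mt_axis[imt, 0]
    hy = mt_center[imt, 1] + (arc - 0.5 * Li) * mt_axis[imt, 1]
    hz = mt_center[imt, 2] + (arc - 0.5 * Li) * mt_axis[imt, 2]
    uix, uiy, uiz = mt_axis[imt, 0], mt_axis[imt, 1], mt_axis[imt, 2]
    total = 0.0
    M = mt_center.shape[0]
    for j in range(M):
        if j == imt:
            continue
        L = mt_len[j]
        ux, uy, uz = mt_axis[j, 0], mt_axis[j, 1], mt_axis[j, 2]
        mx = mt_center[j, 0] - 0.5 * L * ux
        my = mt_center[j, 1] - 0.5 * L * uy
        mz = mt_center[j, 2] - 0.5 * L * uz
        px, py, pz = hx - mx, hy - my, hz - mz
        tinf = px * ux + py * uy + pz * uz
        dperp2 = px * px + py * py + pz * pz - tinf * tinf
        w2 = wcut * wcut - dperp2
        if w2 <= 0.0:
            continue
        W = np.sqrt(w2)
        smin = tinf - W
        if smin < 0.0:
            smin = 0.0
        smax = tinf + W
        if smax > L:
            smax = L
        if smax <= smin:
            continue
        aff = 1.0
        if sp == SP_XL and uix * ux + uiy * uy + uiz * uz > 0.0:
            aff = P[IP_XL_PAFF]
        nseg = int((smax - smin) / ds) + 1
        dseg = (smax - smin) / nseg
        pref = c2 * k2o * dseg * aff
        for k in range(nseg):
            s = smin + (k + 0.5) * dseg
            dd = _nrm3(hx - (mx + s * ux), hy - (my + s * uy),
                       hz - (mz + s * uz))
            stretch = dd - r0
            total += pref * _cexp(-0.5 * K * stretch * stretch / kbt)
            if choose and total >= rpick:
                return total, j, s
    return total, -1, 0.0


@njit(cache=True, fastmath=True)
def run_kernel(P, seed, n_steps, sample_stride,
               spb_pos, spb_ang, anchor_local,
               mt_center, mt_axis, mt_len, mt_state, mt_spb, mt_site,
               mt_grow_accum, mt_tip_af,
               kc_pos, kc_n, kc_t,
               af_mode, af_mt, af_pos,
               lk_sp, lk_state, lk_mt, lk_pos,
               sac_state,
               out_t, out_spb, out_kc, out_spindle, out_interkc,
               out_chrom_state, out_class_force, out_bound, out_af_mt,
               out_af_mode, out_mt_len, out_bio, out_ana):
    rs = np.empty(2, dtype=np.uint64)
    gsp = np.zeros(2)
    _seed_state(seed, rs)
    dt = P[IP_DT]
    kbt = P[IP_KBT]
    R = P[IP_RADIUS]
    fmax = P[IP_F_CLAMP]
    eps = P[IP_WCA_EPS]
    soft = P[IP_SOFT_MODE] > 0.5
    M = mt_center.shape[0]
    K = kc_pos.shape[0]
    NC = K // 2
    NL = lk_sp.shape[0]
    NAF = af_mode.shape[0]
    n_refresh = int(P[IP_N_REFRESH])
    stride_k = int(P[IP_KIN_STRIDE])
    dt_l = dt * stride_k           # kinetics timestep
    nkmc = int(P[IP_N_KMC])
    sigma_mt = P[IP_MT_DIAM]
    sigma_mt_spb = 0.5 * (P[IP_MT_DIAM] + P[IP_SPB_DIAM])
    sigma_kc_mt = 0.5 * (P[IP_KC_WID] + P[IP_MT_DIAM])
    sigma_cmt = 0.5 * (P[IP_CHROM_DIAM] + P[IP_MT_DIAM])
    kc_seg = P[IP_KC_LEN] - P[IP_KC_WID]
    chrom_seg = P[IP_CHROM_LEN] - P[IP_CHROM_DIAM]
    if chrom_seg < 0.0:
        chrom_seg = 0.0
    k0_teth = P[IP_SPB_K0_SOFT] if soft else P[IP_SPB_K0]
    spb_mu = P[IP_SPB_DT] / kbt
    kc_mu = 1.0 / P[IP_KC_GT]
    kc_mur = 1.0 / P[IP_KC_GR]
    eta = P[IP_ETA]
    l_min = P[IP_L_MIN]
    tip_len = P[IP_TIP_LEN]
    cut_mm = 1.1225 * sigma_mt
    volume = 4.0 / 3.0 * np.pi * R * R * R
    kc_noise_t = np.sqrt(2.0 * kc_mu * kbt * dt)
    kc_noise_r = np.sqrt(2.0 * kc_mur * kbt * dt)
    spb_noise = np.sqrt(2.0 * P[IP_SPB_DT] * dt)
    spb_rot_noise = np.sqrt(2.0 * P[IP_SPB_DR] * dt)

    # scratch
    f_mt = np.zeros((M, 3))
    t_mt = np.zeros((M, 3))
    f_kc = np.zeros((K, 3))
    t_kc = np.zeros((K, 3))
    f_spb = np.zeros((2, 3))
    tip_comp = np.zeros(M)
    tip_ten = np.zeros(M)
    mt_stab = np.zeros(M, dtype=np.int64)
    mt_lat = np.zeros(M, dtype=np.int64)
    lkf_mt = np.zeros((M, 3))   # cached aggregate linker forces on MTs
    lkt_mt = np.zeros((M, 3))
    lk_tension = np.zeros(NL)
    lk_rate2 = np.zeros(NL)
    lk_ax0 = np.zeros(NL)
    lk_ax1 = np.zeros(NL)
    af_rate = np.zeros(NAF)
    af_tension = np.zeros(NAF)
    af_theta = np.zeros(NAF)
    af_axial = np.zeros(NAF)
    kc_occ = np.zeros(K, dtype=np.int64)
    chrom_state = np.zeros(NC, dtype=np.int64)
    interkc_tension = np.zeros(NC)
    cls_force = np.zeros(4)
    cls_lk = np.zeros(3)
    anchor_e1 = np.zeros((2, 3))
    anchor_e2 = np.zeros((2, 3))
    mtm = np.zeros((M, 3))   # minus ends, refreshed each step

    isamp = 0
    ana = sac_state[1] > 0.5

    for step in range(n_steps):
        sampling = (step % sample_stride) == 0
        kinetics = (step % stride_k) == 0

        # ----- occupancy and classification --------------------------------
        for k in range(K):
            kc_occ[k] = 0
        for i in range(NAF):
            if af_mode[i] != AF_UNBOUND:
                kc_occ[i // 3] += 1
        all_bio = True
        for c in range(NC):
            mask_a = 0
            mask_b = 0
            for s in range(3):
                ia = (2 * c) * 3 + s
                ib = (2 * c + 1) * 3 + s
                if af_mode[ia] != AF_UNBOUND:
                    mask_a |= 1 << mt_spb[af_mt[ia]]
                if af_mode[ib] != AF_UNBOUND:
                    mask_b |= 1 << mt_spb[af_mt[ib]]
            chrom_state[c] = _classify(mask_a, mask_b)
            if chrom_state[c] != CS_AMPHITELIC:
                all_bio = False
        if not ana:
            if all_bio:
                sac_state[0] += dt
            if P[IP_ANA_ON] > 0.5 and sac_state[0] >= P[IP_TAU_SAC]:
                ana = True
                sac_state[1] = 1.0

        # ----- zero accumulators, cache minus ends --------------------------
        for i in range(M):
            f_mt[i, 0] = 0.0
            f_mt[i, 1] = 0.0
            f_mt[i, 2] = 0.0
            t_mt[i, 0] = 0.0
            t_mt[i, 1] = 0.0
            t_mt[i, 2] = 0.0
            tip_comp[i] = 0.0
            tip_ten[i] = 0.0
            mtm[i, 0] = mt_center[i, 0] - 0.5 * mt_len[i] * mt_axis[i, 0]
            mtm[i, 1] = mt_center[i, 1] - 0.5 * mt_len[i] * mt_axis[i, 1]
            mtm[i, 2] = mt_center[i, 2] - 0.5 * mt_len[i] * mt_axis[i, 2]
        for k in range(K):
            f_kc[k, 0] = 0.0
            f_kc[k, 1] = 0.0
            f_kc[k, 2] = 0.0
            t_kc[k, 0] = 0.0
            t_kc[k, 1] = 0.0
            t_kc[k, 2] = 0.0
        for q in range(3):
            f_spb[0, q] = 0.0
            f_spb[1, q] = 0.0
        for c in range(4):
            cls_force[c] = 0.0

        # spindle axis (for the force decomposition)
        axx = spb_pos[1, 0] - spb_pos[0, 0]
        axy = spb_pos[1, 1] - spb_pos[0, 1]
        axz = spb_pos[1, 2] - spb_pos[0, 2]
        axn = _nrm3(axx, axy, axz)
        if axn > 1e-9:
            axx /= axn
            axy /= axn
            axz /= axn
        else:
            axx, axy, axz = 1.0, 0.0, 0.0

        # ----- anchor frames & minus-end tethers ----------------------------
        for ispb in range(2):
            r = _nrm3(spb_pos[ispb, 0], spb_pos[ispb, 1], spb_pos[ispb, 2])
            rx = spb_pos[ispb, 0] / r
            ry = spb_pos[ispb, 1] / r
            rz = spb_pos[ispb, 2] / r
            e1x, e1y, e1z = -ry, rx, 0.0
            n = _nrm3(e1x, e1y, e1z)
            if n < 1e-8:
                e1x, e1y, e1z = 1.0, 0.0, 0.0
            else:
                e1x, e1y, e1z = e1x / n, e1y / n, e1z / n
            e2x = ry * e1z - rz * e1y
            e2y = rz * e1x - rx * e1z
            e2z = rx * e1y - ry * e1x
            ca = np.cos(spb_ang[ispb])
            sa = np.sin(spb_ang[ispb])
            anchor_e1[ispb, 0] = ca * e1x + sa * e2x
            anchor_e1[ispb, 1] = ca * e1y + sa * e2y
            anchor_e1[ispb, 2] = ca * e1z + sa * e2z
            anchor_e2[ispb, 0] = -sa * e1x + ca * e2x
            anchor_e2[ispb, 1] = -sa * e1y + ca * e2y
            anchor_e2[ispb, 2] = -sa * e1z + ca * e2z
        for i in range(M):
            ispb = mt_spb[i]
            s_i = mt_site[i]
            a1 = anchor_local[ispb, s_i, 0]
            a2 = anchor_local[ispb, s_i, 1]
            ax0 = spb_pos[ispb, 0] + a1 * anchor_e1[ispb, 0] + a2 * anchor_e2[ispb, 0]
            ay0 = spb_pos[ispb, 1] + a1 * anchor_e1[ispb, 1] + a2 * anchor_e2[ispb, 1]
            az0 = spb_pos[ispb, 2] + a1 * anchor_e1[ispb, 2] + a2 * anchor_e2[ispb, 2]
            dx = ax0 - mtm[i, 0]
            dy = ay0 - mtm[i, 1]
            dz = az0 - mtm[i, 2]
            d = _nrm3(dx, dy, dz)
            if d > 1e-9:
                fmag = k0_teth * (d - P[IP_SPB_R0]) / d
                fx = fmag * dx
                fy = fmag * dy
                fz = fmag * dz
                f_mt[i, 0] += fx
                f_mt[i, 1] += fy
                f_mt[i, 2] += fz
                rx = mtm[i, 0] - mt_center[i, 0]
                ry = mtm[i, 1] - mt_center[i, 1]
                rz = mtm[i, 2] - mt_center[i, 2]
                t_mt[i, 0] += ry * fz - rz * fy
                t_mt[i, 1] += rz * fx - rx * fz
                t_mt[i, 2] += rx * fy - ry * fx
                f_spb[ispb, 0] -= fx
                f_spb[ispb, 1] -= fy
                f_spb[ispb, 2] -= fz

        # ----- MT-MT sterics -------------------------------------------------
        for i in range(M):
            Li = mt_len[i]
            for j in range(i + 1, M):
                Lj = mt_len[j]
                dcx = mt_center[i, 0] - mt_center[j, 0]
                dcy = mt_center[i, 1] - mt_center[j, 1]
                dcz = mt_center[i, 2] - mt_center[j, 2]
                if _nrm3(dcx, dcy, dcz) > 0.5 * (Li + Lj) + cut_mm:
                    continue
                si, sj, d, pax, pay, paz, pbx, pby, pbz = _segseg(
                    mtm[i, 0], mtm[i, 1], mtm[i, 2],
                    mt_axis[i, 0], mt_axis[i, 1], mt_axis[i, 2], Li,
                    mtm[j, 0], mtm[j, 1], mtm[j, 2],
                    mt_axis[j, 0], mt_axis[j, 1], mt_axis[j, 2], Lj)
                if d >= cut_mm:
                    continue
                fm = _wca(d - sigma_mt, sigma_mt, eps, fmax)
                if fm <= 0.0 or d < 1e-9:
                    continue
                fx = fm * (pax - pbx) / d
                fy = fm * (pay - pby) / d
                fz = fm * (paz - pbz) / d
                f_mt[i, 0] += fx
                f_mt[i, 1] += fy
                f_mt[i, 2] += fz
                f_mt[j, 0] -= fx
                f_mt[j, 1] -= fy
                f_mt[j, 2] -= fz
                rx = pax - mt_center[i, 0]
                ry = pay - mt_center[i, 1]
                rz = paz - mt_center[i, 2]
                t_mt[i, 0] += ry * fz - rz * fy
                t_mt[i, 1] += rz * fx - rx * fz
                t_mt[i, 2] += rx * fy - ry * fx
                rx = pbx - mt_center[j, 0]
                ry = pby - mt_center[j, 1]
                rz = pbz - mt_center[j, 2]
                t_mt[j, 0] -= ry * fz - rz * fy
                t_mt[j, 1] -= rz * fx - rx * fz
                t_mt[j, 2] -= rx * fy - ry * fx
                if si > Li - tip_len:
                    ac = -(fx * mt_axis[i, 0] + fy * mt_axis[i, 1]
                           + fz * mt_axis[i, 2])
                    if ac > 0.0:
                        tip_comp[i] += ac
                if sj > Lj - tip_len:
                    ac = (fx * mt_axis[j, 0] + fy * mt_axis[j, 1]
                          + fz * mt_axis[j, 2])
                    if ac > 0.0:
                        tip_comp[j] += ac

        # ----- MT vs opposite SPB, SPB-SPB sterics ---------------------------
        for i in range(M):
            other = 1 - mt_spb[i]
            L = mt_len[i]
            s, d, qx, qy, qz = _ptseg(
                spb_pos[other, 0], spb_pos[other, 1], spb_pos[other, 2],
                mtm[i, 0], mtm[i, 1], mtm[i, 2],
                mt_axis[i, 0], mt_axis[i, 1], mt_axis[i, 2], L)
            fm = _wca(d - sigma_mt_spb, sigma_mt_spb, eps, fmax)
            if fm > 0.0 and d > 1e-9:
                fx = fm * (qx - spb_pos[other, 0]) / d
                fy = fm * (qy - spb_pos[other, 1]) / d
                fz = fm * (qz - spb_pos[other, 2]) / d
                f_mt[i, 0] += fx
                f_mt[i, 1] += fy
                f_mt[i, 2] += fz
                f_spb[other, 0] -= fx
                f_spb[other, 1] -= fy
                f_spb[other, 2] -= fz
                rx = qx - mt_center[i, 0]
                ry = qy - mt_center[i, 1]
                rz = qz - mt_center[i, 2]
                t_mt[i, 0] += ry * fz - rz * fy
                t_mt[i, 1] += rz * fx - rx * fz
                t_mt[i, 2] += rx * fy - ry * fx
                if s > L - tip_len:
                    ac = -(fx * mt_axis[i, 0] + fy * mt_axis[i, 1]
                           + fz * mt_axis[i, 2])
                    if ac > 0.0:
                        tip_comp[i] += ac
        dx = spb_pos[0, 0] - spb_pos[1, 0]
        dy = spb_pos[0, 1] - spb_pos[1, 1]
        dz = spb_pos[0, 2] - spb_pos[1, 2]
        d = _nrm3(dx, dy, dz)
        # duplicated-SPB bridge: holds the pair at the bridge separation
        # until the linkage dissolves at tau_link
        if step * dt < P[IP_TAU_LINK] and d > 1e-9:
            fl = P[IP_SPB_K0] * (d - P[IP_BRIDGE]) / d
            f_spb[0, 0] -= fl * dx
            f_spb[0, 1] -= fl * dy
            f_spb[0, 2] -= fl * dz
            f_spb[1, 0] += fl * dx
            f_spb[1, 1] += fl * dy
            f_spb[1, 2] += fl * dz
        fm = _wca(d - P[IP_BRIDGE], P[IP_BRIDGE], eps, fmax)
        if fm > 0.0 and d > 1e-9:
            f_spb[0, 0] += fm * dx / d
            f_spb[0, 1] += fm * dy / d
            f_spb[0, 2] += fm * dz / d
            f_spb[1, 0] -= fm * dx / d
            f_spb[1, 1] -= fm * dy / d
            f_spb[1, 2] -= fm * dz / d

        # ----- envelope confinement of MT plus ends --------------------------
        for i in range(M):
            L = mt_len[i]
            px = mtm[i, 0] + L * mt_axis[i, 0]
            py = mtm[i, 1] + L * mt_axis[i, 1]
            pz = mtm[i, 2] + L * mt_axis[i, 2]
            r = _nrm3(px, py, pz)
            if r <= R or r < 1e-9:
                continue
            exc = r - R
            if soft:
                fm = P[IP_F_MT_WALL] * np.tanh(exc / P[IP_FTUBE])
            else:
                fm = P[IP_WALL_K] * exc
                if fm > fmax:
                    fm = fmax
            fx = -fm * px / r
            fy = -fm * py / r
            fz = -fm * pz / r
            f_mt[i, 0] += fx
            f_mt[i, 1] += fy
            f_mt[i, 2] += fz
            rx = px - mt_center[i, 0]
            ry = py - mt_center[i, 1]
            rz = pz - mt_center[i, 2]
            t_mt[i, 0] += ry * fz - rz * fy
            t_mt[i, 1] += rz * fx - rx * fz
            t_mt[i, 2] += rx * fy - ry * fx
            ac = -(fx * mt_axis[i, 0] + fy * mt_axis[i, 1] + fz * mt_axis[i, 2])
            if ac > 0.0:
                tip_comp[i] += ac

        # ----- kinetochore plates: steric with MTs, confinement --------------
        for k in range(K):
            bx = kc_pos[k, 0] - 0.5 * kc_seg * kc_t[k, 0]
            by = kc_pos[k, 1] - 0.5 * kc_seg * kc_t[k, 1]
            bz = kc_pos[k, 2] - 0.5 * kc_seg * kc_t[k, 2]
            for i in range(M):
                Li = mt_len[i]
                dcx = mt_center[i, 0] - kc_pos[k, 0]
                dcy = mt_center[i, 1] - kc_pos[k, 1]
                dcz = mt_center[i, 2] - kc_pos[k, 2]
                if _nrm3(dcx, dcy, dcz) > 0.5 * Li + kc_seg + 2.0 * sigma_kc_mt:
                    continue
                si, sk, d, pax, pay, paz, pbx, pby, pbz = _segseg(
                    mtm[i, 0], mtm[i, 1], mtm[i, 2],
                    mt_axis[i, 0], mt_axis[i, 1], mt_axis[i, 2], Li,
                    bx, by, bz,
                    kc_t[k, 0], kc_t[k, 1], kc_t[k, 2], kc_seg)
                fm = _wca(d - sigma_kc_mt, sigma_kc_mt, eps, fmax)
                if fm <= 0.0 or d < 1e-9:
                    continue
                fx = fm * (pax - pbx) / d
                fy = fm * (pay - pby) / d
                fz = fm * (paz - pbz) / d
                f_mt[i, 0] += fx
                f_mt[i, 1] += fy
                f_mt[i, 2] += fz
                f_kc[k, 0] -= fx
                f_kc[k, 1] -= fy
                f_kc[k, 2] -= fz
                rx = pax - mt_center[i, 0]
                ry = pay - mt_center[i, 1]
                rz = paz - mt_center[i, 2]
                t_mt[i, 0] += ry * fz - rz * fy
                t_mt[i, 1] += rz * fx - rx * fz
                t_mt[i, 2] += rx * fy - ry * fx
                rx = pbx - kc_pos[k, 0]
                ry = pby - kc_pos[k, 1]
                rz = pbz - kc_pos[k, 2]
                t_kc[k, 0] -= ry * fz - rz * fy
                t_kc[k, 1] -= rz * fx - rx * fz
                t_kc[k, 2] -= rx * fy - ry * fx
                if si > Li - tip_len:
                    ac = -(fx * mt_axis[i, 0] + fy * mt_axis[i, 1]
                           + fz * mt_axis[i, 2])
                    if ac > 0.0:
                        # kinetochore contact promotes catastrophe like the wall
                        tip_comp[i] += ac * P[IP_KC_FC_ENH] / P[IP_ALPHA_C]
            r = _nrm3(kc_pos[k, 0], kc_pos[k, 1], kc_pos[k, 2])
            if r > R - 50.0 and r > 1e-9:
                fm = P[IP_WALL_K] * (r - (R - 50.0))
                f_kc[k, 0] -= fm * kc_pos[k, 0] / r
                f_kc[k, 1] -= fm * kc_pos[k, 1] / r
                f_kc[k, 2] -= fm * kc_pos[k, 2] / r

        # ----- pericentric chromatin soft repulsion --------------------------
        for c in range(NC):
            ka = 2 * c
            kb = 2 * c + 1
            cx = 0.5 * (kc_pos[ka, 0] + kc_pos[kb, 0])
            cy = 0.5 * (kc_pos[ka, 1] + kc_pos[kb, 1])
            cz = 0.5 * (kc_pos[ka, 2] + kc_pos[kb, 2])
            ux = kc_pos[kb, 0] - kc_pos[ka, 0]
            uy = kc_pos[kb, 1] - kc_pos[ka, 1]
            uz = kc_pos[kb, 2] - kc_pos[ka, 2]
            un = _nrm3(ux, uy, uz)
            if un < 1e-9:
                ux, uy, uz = kc_n[ka, 0], kc_n[ka, 1], kc_n[ka, 2]
            else:
                ux, uy, uz = ux / un, uy / un, uz / un
            bx = cx - 0.5 * chrom_seg * ux
            by = cy - 0.5 * chrom_seg * uy
            bz = cz - 0.5 * chrom_seg * uz
            for i in range(M):
                Li = mt_len[i]
                dcx = mt_center[i, 0] - cx
                dcy = mt_center[i, 1] - cy
                dcz = mt_center[i, 2] - cz
                if _nrm3(dcx, dcy, dcz) > 0.5 * Li + chrom_seg + 2.0 * sigma_cmt:
                    continue
                si, sc, d, pax, pay, paz, pbx, pby, pbz = _segseg(
                    mtm[i, 0], mtm[i, 1], mtm[i, 2],
                    mt_axis[i, 0], mt_axis[i, 1], mt_axis[i, 2], Li,
                    bx, by, bz, ux, uy, uz, chrom_seg)
                sd = d - sigma_cmt
                if sd >= 0.0 or d < 1e-9:
                    continue
                delta = -sd
                if delta > sigma_cmt:
                    delta = sigma_cmt
                fm = 2.0 * P[IP_A_CMT] * delta / (sigma_cmt * sigma_cmt)
                fx = fm * (pax - pbx) / d
                fy = fm * (pay - pby) / d
                fz = fm * (paz - pbz) / d
                f_mt[i, 0] += fx
                f_mt[i, 1] += fy
                f_mt[i, 2] += fz
                f_kc[ka, 0] -= 0.5 * fx
                f_kc[ka, 1] -= 0.5 * fy
                f_kc[ka, 2] -= 0.5 * fz
                f_kc[kb, 0] -= 0.5 * fx
                f_kc[kb, 1] -= 0.5 * fy
                f_kc[kb, 2] -= 0.5 * fz

        # ----- interkinetochore springs --------------------------------------
        for c in range(NC):
            interkc_tension[c] = 0.0
            if ana:
                continue  # springs severed
            ka = 2 * c
            kb = 2 * c + 1
            dxk = kc_pos[kb, 0] - kc_pos[ka, 0]
            dyk = kc_pos[kb, 1] - kc_pos[ka, 1]
            dzk = kc_pos[kb, 2] - kc_pos[ka, 2]
            r = _nrm3(dxk, dyk, dzk)
            if r < 1e-9:
                continue
            ux, uy, uz = dxk / r, dyk / r, dzk / r
            fmag = P[IP_KAPPA_C] * (r - P[IP_RC0])
            if fmag > 0.0:
                interkc_tension[c] = fmag
            f_kc[ka, 0] += fmag * ux
            f_kc[ka, 1] += fmag * uy
            f_kc[ka, 2] += fmag * uz
            f_kc[kb, 0] -= fmag * ux
            f_kc[kb, 1] -= fmag * uy
            f_kc[kb, 2] -= fmag * uz
            for pair in range(2):
                kk = ka if pair == 0 else kb
                tx = -ux if pair == 0 else ux
                ty = -uy if pair == 0 else uy
                tz = -uz if pair == 0 else uz
                cth = kc_n[kk, 0] * tx + kc_n[kk, 1] * ty + kc_n[kk, 2] * tz
                if cth > 1.0:
                    cth = 1.0
                elif cth < -1.0:
                    cth = -1.0
                th = np.arccos(cth)
                wx = kc_n[kk, 1] * tz - kc_n[kk, 2] * ty
                wy = kc_n[kk, 2] * tx - kc_n[kk, 0] * tz
                wz = kc_n[kk, 0] * ty - kc_n[kk, 1] * tx
                an = _nrm3(wx, wy, wz)
                if an > 1e-9:
                    tq = P[IP_KAPPA_CU] * th / an
                    t_kc[kk, 0] += tq * wx
                    t_kc[kk, 1] += tq * wy
                    t_kc[kk, 2] += tq * wz
            dtt = (kc_t[ka, 0] * kc_t[kb, 0] + kc_t[ka, 1] * kc_t[kb, 1]
                   + kc_t[ka, 2] * kc_t[kb, 2])
            sgn = 1.0 if dtt >= 0.0 else -1.0
            tx = sgn * kc_t[kb, 0]
            ty = sgn * kc_t[kb, 1]
            tz = sgn * kc_t[kb, 2]
            cth = kc_t[ka, 0] * tx + kc_t[ka, 1] * ty + kc_t[ka, 2] * tz
            if cth > 1.0:
                cth = 1.0
            elif cth < -1.0:
                cth = -1.0
            th = np.arccos(cth)
            wx = kc_t[ka, 1] * tz - kc_t[ka, 2] * ty
            wy = kc_t[ka, 2] * tx - kc_t[ka, 0] * tz
            wz = kc_t[ka, 0] * ty - kc_t[ka, 1] * tx
            an = _nrm3(wx, wy, wz)
            if an > 1e-9:
                tq = P[IP_KAPPA_CV] * th / an
                t_kc[ka, 0] += tq * wx
                t_kc[ka, 1] += tq * wy
                t_kc[ka, 2] += tq * wz
                t_kc[kb, 0] -= tq * wx
                t_kc[kb, 1] -= tq * wy
                t_kc[kb, 2] -= tq * wz

        # ----- attachment-factor tethers and angular springs -----------------
        for i in range(NAF):
            if af_mode[i] == AF_UNBOUND:
                af_tension[i] = 0.0
                af_theta[i] = 0.0
                af_axial[i] = 0.0
                continue
            k = i // 3
            slot = i % 3
            off = (slot - 1) * P[IP_SITE_SEP]
            sx = kc_pos[k, 0] + off * kc_t[k, 0]
            sy = kc_pos[k, 1] + off * kc_t[k, 1]
            sz = kc_pos[k, 2] + off * kc_t[k, 2]
            j = af_mt[i]
            L = mt_len[j]
            arc = af_pos[i]
            if arc > L:
                arc = L
                af_pos[i] = L
            hx = mtm[j, 0] + arc * mt_axis[j, 0]
            hy = mtm[j, 1] + arc * mt_axis[j, 1]
            hz = mtm[j, 2] + arc * mt_axis[j, 2]
            dx = sx - hx
            dy = sy - hy
            dz = sz - hz
            d = _nrm3(dx, dy, dz)
            if d > 1e-9:
                tsg = P[IP_AF_KM] * (d - P[IP_AF_R0])
                fx = tsg * dx / d
                fy = tsg * dy / d
                fz = tsg * dz / d
            else:
                tsg, fx, fy, fz = 0.0, 0.0, 0.0, 0.0
            af_tension[i] = tsg if tsg > 0.0 else 0.0
            aax = fx * mt_axis[j, 0] + fy * mt_axis[j, 1] + fz * mt_axis[j, 2]
            af_axial[i] = aax
            f_mt[j, 0] += fx
            f_mt[j, 1] += fy
            f_mt[j, 2] += fz
            rx = hx - mt_center[j, 0]
            ry = hy - mt_center[j, 1]
            rz = hz - mt_center[j, 2]
            t_mt[j, 0] += ry * fz - rz * fy
            t_mt[j, 1] += rz * fx - rx * fz
            t_mt[j, 2] += rx * fy - ry * fx
            f_kc[k, 0] -= fx
            f_kc[k, 1] -= fy
            f_kc[k, 2] -= fz
            rx = sx - kc_pos[k, 0]
            ry = sy - kc_pos[k, 1]
            rz = sz - kc_pos[k, 2]
            t_kc[k, 0] -= ry * fz - rz * fy
            t_kc[k, 1] -= rz * fx - rx * fz
            t_kc[k, 2] -= rx * fy - ry * fx
            if af_mode[i] == AF_ENDON and aax > 0.0:
                tip_ten[j] += aax
            if sampling:
                sgn = 1.0 if mt_spb[j] == 1 else -1.0
                cls_force[3] += 0.5 * sgn * (fx * axx + fy * axy + fz * axz)
            occ = kc_occ[k]
            if occ <= 1:
                kap = P[IP_AF_KR1] if occ == 1 else P[IP_AF_KR0]
            elif occ == 2:
                kap = P[IP_AF_KR2]
            else:
                kap = P[IP_AF_KR3]
            cu = -(mt_axis[j, 0] * kc_n[k, 0] + mt_axis[j, 1] * kc_n[k, 1]
                   + mt_axis[j, 2] * kc_n[k, 2])
            if cu > 1.0:
                cu = 1.0
            elif cu < -1.0:
                cu = -1.0
            th = np.arccos(cu)
            af_theta[i] = th
            crx = -(mt_axis[j, 1] * kc_n[k, 2] - mt_axis[j, 2] * kc_n[k, 1])
            cry = -(mt_axis[j, 2] * kc_n[k, 0] - mt_axis[j, 0] * kc_n[k, 2])
            crz = -(mt_axis[j, 0] * kc_n[k, 1] - mt_axis[j, 1] * kc_n[k, 0])
            cn = _nrm3(crx, cry, crz)
            if cn > 1e-9:
                tq = kap * th / cn
                t_mt[j, 0] += tq * crx
                t_mt[j, 1] += tq * cry
                t_mt[j, 2] += tq * crz
                t_kc[k, 0] -= tq * crx
                t_kc[k, 1] -= tq * cry
                t_kc[k, 2] -= tq * crz

        # ----- doubly bound linker springs -----------------------------------
        # Spring relaxation is slow compared to the kinetics stride, so the
        # per-MT aggregate of linker forces/torques (and the per-class axial
        # force sums) is cached and recomputed on kinetics steps only.
        if kinetics:
            cls_lk[0] = 0.0
            cls_lk[1] = 0.0
            cls_lk[2] = 0.0
            for i in range(M):
                for q in range(3):
                    lkf_mt[i, q] = 0.0
                    lkt_mt[i, q] = 0.0
            for il in range(NL):
                if lk_state[il] != LK_BOTH:
                    lk_tension[il] = 0.0
                    lk_ax0[il] = 0.0
                    lk_ax1[il] = 0.0
                    continue
                sp = lk_sp[il]
                if sp == SP_K5:
                    Ks = P[IP_K5_K]
                    r0s = P[IP_K5_R0]
                elif sp == SP_K14:
                    Ks = P[IP_K14_K]
                    r0s = P[IP_K14_R0]
                else:
                    Ks = P[IP_XL_K]
                    r0s = P[IP_XL_R0]
                i0 = lk_mt[il, 0]
                i1 = lk_mt[il, 1]
                p0 = lk_pos[il, 0]
                p1 = lk_pos[il, 1]
                h0x = mtm[i0, 0] + p0 * mt_axis[i0, 0]
                h0y = mtm[i0, 1] + p0 * mt_axis[i0, 1]
                h0z = mtm[i0, 2] + p0 * mt_axis[i0, 2]
                h1x = mtm[i1, 0] + p1 * mt_axis[i1, 0]
                h1y = mtm[i1, 1] + p1 * mt_axis[i1, 1]
                h1z = mtm[i1, 2] + p1 * mt_axis[i1, 2]
                dx = h1x - h0x
                dy = h1y - h0y
                dz = h1z - h0z
                d = _nrm3(dx, dy, dz)
                if d < 1e-9:
                    lk_tension[il] = 0.0
                    lk_ax0[il] = 0.0
                    lk_ax1[il] = 0.0
                    continue
                tsg = Ks * (d - r0s)
                lk_tension[il] = tsg if tsg > 0.0 else 0.0
                fx = tsg * dx / d
                fy = tsg * dy / d
                fz = tsg * dz / d
                lk_ax0[il] = fx * mt_axis[i0, 0] + fy * mt_axis[i0, 1] + fz * mt_axis[i0, 2]
                lk_ax1[il] = -(fx * mt_axis[i1, 0] + fy * mt_axis[i1, 1]
                               + fz * mt_axis[i1, 2])
                lkf_mt[i0, 0] += fx
                lkf_mt[i0, 1] += fy
                lkf_mt[i0, 2] += fz
                lkf_mt[i1, 0] -= fx
                lkf_mt[i1, 1] -= fy
                lkf_mt[i1, 2] -= fz
                rx = h0x - mt_center[i0, 0]
                ry = h0y - mt_center[i0, 1]
                rz = h0z - mt_center[i0, 2]
                lkt_mt[i0, 0] += ry * fz - rz * fy
                lkt_mt[i0, 1] += rz * fx - rx * fz
                lkt_mt[i0, 2] += rx * fy - ry * fx
                rx = h1x - mt_center[i1, 0]
                ry = h1y - mt_center[i1, 1]
                rz = h1z - mt_center[i1, 2]
                lkt_mt[i1, 0] -= ry * fz - rz * fy
                lkt_mt[i1, 1] -= rz * fx - rx * fz
                lkt_mt[i1, 2] -= rx * fy - ry * fx
                if mt_spb[i0] != mt_spb[i1]:
                    s0 = 1.0 if mt_spb[i0] == 1 else -1.0
                    ax_comp = fx * axx + fy * axy + fz * axz
                    # outward force on each half; the two halves average
                    cls_lk[sp] += s0 * ax_comp
            for i in range(M):
                for q in range(3):
                    f_mt[i, q] += lkf_mt[i, q]
                    t_mt[i, q] += lkt_mt[i, q]
        else:
            for i in range(M):
                for q in range(3):
                    f_mt[i, q] += lkf_mt[i, q]
                    t_mt[i, q] += lkt_mt[i, q]

        # ----- stabilization / engagement flags ------------------------------
        for i in range(M):
            mt_stab[i] = 0
            mt_lat[i] = 0
        for il in range(NL):
            if lk_sp[il] == SP_XL and lk_state[il] == LK_BOTH:
                for h in range(2):
                    j = lk_mt[il, h]
                    if lk_pos[il, h] >= mt_len[j] - P[IP_S_L]:
                        mt_stab[j] = 1
        for i in range(NAF):
            if af_mode[i] == AF_LATERAL:
                mt_lat[af_mt[i]] = 1

        # ----- sampling ------------------------------------------------------
        if sampling:
            out_t[isamp] = step * dt
            for q in range(3):
                out_spb[isamp, 0, q] = spb_pos[0, q]
                out_spb[isamp, 1, q] = spb_pos[1, q]
            sl = _nrm3(spb_pos[1, 0] - spb_pos[0, 0],
                       spb_pos[1, 1] - spb_pos[0, 1],
                       spb_pos[1, 2] - spb_pos[0, 2])
            out_spindle[isamp] = sl
            mlm = 0.0
            for i in range(M):
                mlm += mt_len[i]
            out_mt_len[isamp] = mlm / M
            for k in range(K):
                for q in range(3):
                    out_kc[isamp, k, q] = kc_pos[k, q]
            for c in range(NC):
                out_interkc[isamp, c] = _nrm3(
                    kc_pos[2 * c + 1, 0] - kc_pos[2 * c, 0],
                    kc_pos[2 * c + 1, 1] - kc_pos[2 * c, 1],
                    kc_pos[2 * c + 1, 2] - kc_pos[2 * c, 2])
                out_chrom_state[isamp, c] = chrom_state[c]
            for c in range(3):
                out_class_force[isamp, c] = cls_lk[c]
            out_class_force[isamp, 3] = cls_force[3]
            for spv in range(3):
                nfree = 0
                none_ = 0
                ntwo = 0
                for il in range(NL):
                    if lk_sp[il] != spv:
                        continue
                    if lk_state[il] == LK_FREE:
                        nfree += 1
                    elif lk_state[il] == LK_BOTH:
                        ntwo += 1
                    else:
                        none_ += 1
                out_bound[isamp, spv, 0] = nfree
                out_bound[isamp, spv, 1] = none_
                out_bound[isamp, spv, 2] = ntwo
            for i in range(NAF):
                out_af_mt[isamp, i] = af_mt[i] if af_mode[i] != AF_UNBOUND else -1
                out_af_mode[isamp, i] = af_mode[i]
            out_bio[isamp] = sac_state[0]
            out_ana[isamp] = 1.0 if ana else 0.0
            if np.isnan(sl) or np.isnan(mlm):
                return STATUS_NAN, isamp + 1
            isamp += 1

        # ----- BD update: MTs ------------------------------------------------
        for i in range(M):
            L = mt_len[i]
            lam = np.log(L / sigma_mt)
            if lam < 0.5:
                lam = 0.5
            g_par = 2.0 * np.pi * eta * L / lam
            mu_par = 1.0 / g_par
            mu_perp = 0.5 * mu_par
            mu_rot = 3.0 * lam / (np.pi * eta * L * L * L)
            ux, uy, uz = mt_axis[i, 0], mt_axis[i, 1], mt_axis[i, 2]
            fx, fy, fz = f_mt[i, 0], f_mt[i, 1], f_mt[i, 2]
            fn = _nrm3(fx, fy, fz)
            if fn > fmax:
                sc = fmax / fn
                fx *= sc
                fy *= sc
                fz *= sc
            fpar = fx * ux + fy * uy + fz * uz
            gx = _randn(rs, gsp)
            gy = _randn(rs, gsp)
            gz = _randn(rs, gsp)
            gpar = gx * ux + gy * uy + gz * uz
            npar = np.sqrt(2.0 * mu_par * kbt * dt)
            nperp = np.sqrt(2.0 * mu_perp * kbt * dt)
            mt_center[i, 0] += (mu_par * fpar * ux + mu_perp * (fx - fpar * ux)) * dt \
                + npar * gpar * ux + nperp * (gx - gpar * ux)
            mt_center[i, 1] += (mu_par * fpar * uy + mu_perp * (fy - fpar * uy)) * dt \
                + npar * gpar * uy + nperp * (gy - gpar * uy)
            mt_center[i, 2] += (mu_par * fpar * uz + mu_perp * (fz - fpar * uz)) * dt \
                + npar * gpar * uz + nperp * (gz - gpar * uz)
            nrot = np.sqrt(2.0 * mu_rot * kbt * dt)
            wx = mu_rot * t_mt[i, 0] * dt + nrot * _randn(rs, gsp)
            wy = mu_rot * t_mt[i, 1] * dt + nrot * _randn(rs, gsp)
            wz = mu_rot * t_mt[i, 2] * dt + nrot * _randn(rs, gsp)
            nux = ux + wy * uz - wz * uy
            nuy = uy + wz * ux - wx * uz
            nuz = uz + wx * uy - wy * ux
            nn = _nrm3(nux, nuy, nuz)
            mt_axis[i, 0] = nux / nn
            mt_axis[i, 1] = nuy / nn
            mt_axis[i, 2] = nuz / nn

        # ----- BD update: kinetochores ---------------------------------------
        for k in range(K):
            fx, fy, fz = f_kc[k, 0], f_kc[k, 1], f_kc[k, 2]
            fn = _nrm3(fx, fy, fz)
            if fn > fmax:
                sc = fmax / fn
                fx *= sc
                fy *= sc
                fz *= sc
            kc_pos[k, 0] += kc_mu * fx * dt + kc_noise_t * _randn(rs, gsp)
            kc_pos[k, 1] += kc_mu * fy * dt + kc_noise_t * _randn(rs, gsp)
            kc_pos[k, 2] += kc_mu * fz * dt + kc_noise_t * _randn(rs, gsp)
            wx = kc_mur * t_kc[k, 0] * dt + kc_noise_r * _randn(rs, gsp)
            wy = kc_mur * t_kc[k, 1] * dt + kc_noise_r * _randn(rs, gsp)
            wz = kc_mur * t_kc[k, 2] * dt + kc_noise_r * _randn(rs, gsp)
            nx = kc_n[k, 0] + wy * kc_n[k, 2] - wz * kc_n[k, 1]
            ny = kc_n[k, 1] + wz * kc_n[k, 0] - wx * kc_n[k, 2]
            nz = kc_n[k, 2] + wx * kc_n[k, 1] - wy * kc_n[k, 0]
            nn = _nrm3(nx, ny, nz)
            kc_n[k, 0] = nx / nn
            kc_n[k, 1] = ny / nn
            kc_n[k, 2] = nz / nn
            tx = kc_t[k, 0] + wy * kc_t[k, 2] - wz * kc_t[k, 1]
            ty = kc_t[k, 1] + wz * kc_t[k, 0] - wx * kc_t[k, 2]
            tz = kc_t[k, 2] + wx * kc_t[k, 1] - wy * kc_t[k, 0]
            dot_tn = tx * kc_n[k, 0] + ty * kc_n[k, 1] + tz * kc_n[k, 2]
            tx -= dot_tn * kc_n[k, 0]
            ty -= dot_tn * kc_n[k, 1]
            tz -= dot_tn * kc_n[k, 2]
            nn = _nrm3(tx, ty, tz)
            kc_t[k, 0] = tx / nn
            kc_t[k, 1] = ty / nn
            kc_t[k, 2] = tz / nn

        # ----- BD update: SPBs -----------------------------------------------
        for ispb in range(2):
            r = _nrm3(spb_pos[ispb, 0], spb_pos[ispb, 1], spb_pos[ispb, 2])
            rx = spb_pos[ispb, 0] / r
            ry = spb_pos[ispb, 1] / r
            rz = spb_pos[ispb, 2] / r
            fx, fy, fz = f_spb[ispb, 0], f_spb[ispb, 1], f_spb[ispb, 2]
            fn = _nrm3(fx, fy, fz)
            if fn > fmax:
                sc = fmax / fn
                fx *= sc
                fy *= sc
                fz *= sc
            if not soft:
                frad = fx * rx + fy * ry + fz * rz
                fx -= frad * rx
                fy -= frad * ry
                fz -= frad * rz
                gx = _randn(rs, gsp)
                gy = _randn(rs, gsp)
                gz = _randn(rs, gsp)
                grad = gx * rx + gy * ry + gz * rz
                spb_pos[ispb, 0] += spb_mu * fx * dt + spb_noise * (gx - grad * rx)
                spb_pos[ispb, 1] += spb_mu * fy * dt + spb_noise * (gy - grad * ry)
                spb_pos[ispb, 2] += spb_mu * fz * dt + spb_noise * (gz - grad * rz)
                rr = _nrm3(spb_pos[ispb, 0], spb_pos[ispb, 1], spb_pos[ispb, 2])
                spb_pos[ispb, 0] *= R / rr
                spb_pos[ispb, 1] *= R / rr
                spb_pos[ispb, 2] *= R / rr
            else:
                exc = r - R
                wf = P[IP_F_SPB_WALL] * np.tanh(abs(exc) / P[IP_FTUBE])
                sgn = -1.0 if exc > 0.0 else 1.0
                fx += sgn * wf * rx
                fy += sgn * wf * ry
                fz += sgn * wf * rz
                frad = fx * rx + fy * ry + fz * rz
                mur = P[IP_MOB_RAD]
                mut = P[IP_MOB_TAN]
                nrad = np.sqrt(2.0 * mur * kbt * dt)
                ntan = np.sqrt(2.0 * mut * kbt * dt)
                gx = _randn(rs, gsp)
                gy = _randn(rs, gsp)
                gz = _randn(rs, gsp)
                grad = gx * rx + gy * ry + gz * rz
                spb_pos[ispb, 0] += (mur * frad * rx + mut * (fx - frad * rx)) * dt \
                    + nrad * grad * rx + ntan * (gx - grad * rx)
                spb_pos[ispb, 1] += (mur * frad * ry + mut * (fy - frad * ry)) * dt \
                    + nrad * grad * ry + ntan * (gy - grad * ry)
                spb_pos[ispb, 2] += (mur * frad * rz + mut * (fz - frad * rz)) * dt \
                    + nrad * grad * rz + ntan * (gz - grad * rz)
            spb_ang[ispb] += spb_rot_noise * _randn(rs, gsp)

        # ----- dynamic instability -------------------------------------------
        for i in range(M):
            vg = P[IP_VG0]
            vs = P[IP_VS0]
            fc = P[IP_FC0]
            fr = P[IP_FR0]
            if mt_stab[i] == 1 and P[IP_STAB_ON] > 0.5:
                vg *= P[IP_SVG]
                vs *= P[IP_SVS]
                fc *= P[IP_SFC]
                fr *= P[IP_SFR]
            endon = mt_tip_af[i] >= 0
            attached = endon or mt_lat[i] == 1
            if endon:
                F = tip_ten[i]
                vg *= _cexp(F / P[IP_F_VG])
                vs *= _cexp(F / P[IP_F_VS])
                fc *= _cexp(F / P[IP_F_FC])
                fr *= _cexp(F / P[IP_F_FR])
            if vg > P[IP_V_MT_MAX]:
                vg = P[IP_V_MT_MAX]
            if attached:
                fc *= P[IP_S_DAM1]
            if tip_comp[i] > 0.0:
                fc *= _cexp(P[IP_ALPHA_C] * tip_comp[i])
            if ana and attached:
                mt_state[i] = 0
                vs = P[IP_V_ANA]
                fr = 0.0
            if mt_state[i] == 1:
                dL = vg * dt
                if _u01(rs) < _pevent(fc, dt):
                    mt_state[i] = 0
            else:
                dL = -vs * dt
                if _u01(rs) < _pevent(fr, dt):
                    mt_state[i] = 1
            newL = mt_len[i] + dL
            if newL <= l_min:
                newL = l_min
                mt_state[i] = 1
                dL = newL - mt_len[i]
            mt_len[i] = newL
            mt_center[i, 0] += 0.5 * dL * mt_axis[i, 0]
            mt_center[i, 1] += 0.5 * dL * mt_axis[i, 1]
            mt_center[i, 2] += 0.5 * dL * mt_axis[i, 2]
            iaf = mt_tip_af[i]
            if iaf >= 0:
                if dL < 0.0:
                    af_pos[iaf] = newL
                else:
                    mt_grow_accum[i] += dL
                    stays = True
                    while mt_grow_accum[i] >= P[IP_TRACK_QUANT]:
                        mt_grow_accum[i] -= P[IP_TRACK_QUANT]
                        if _u01(rs) >= P[IP_F_TRACK]:
                            stays = False
                    if stays:
                        af_pos[iaf] = newL
                    else:
                        af_mode[iaf] = AF_LATERAL
                        af_pos[iaf] = newL - mt_grow_accum[i] - P[IP_TRACK_QUANT]
                        if af_pos[iaf] < 0.0:
                            af_pos[iaf] = 0.0
                        mt_tip_af[i] = -1

        # ----- kMC: motors and crosslinkers (kinetics stride) ----------------
        if kinetics:
            total_len = 0.0
            for i in range(M):
                total_len += mt_len[i]
            conc = total_len * P[IP_SITE_DENS] / volume * _UM_PER_NM3
            kon5 = P[IP_K5_KA] * P[IP_K5_K1] * conc
            kon14m = P[IP_K14_KA_M] * P[IP_K14_K1M] * conc
            kon14d = P[IP_K14_KA_D] * P[IP_K14_K1D] * conc
            konxl = P[IP_XL_KA] * P[IP_XL_K1] * conc
            # stage-1 binding: binomial over the (interchangeable) free pool
            nfree5 = 0
            nfree14 = 0
            nfreexl = 0
            for il in range(NL):
                if lk_state[il] == LK_FREE:
                    if lk_sp[il] == SP_K5:
                        nfree5 += 1
                    elif lk_sp[il] == SP_K14:
                        nfree14 += 1
                    else:
                        nfreexl += 1
            nb5 = _binom(rs, nfree5, _pevent(kon5, dt_l)) \
                if nfree5 > 0 else 0
            nb14 = _binom(rs, nfree14, _pevent(kon14m + kon14d, dt_l)) \
                if nfree14 > 0 else 0
            nbxl = _binom(rs, nfreexl, _pevent(konxl, dt_l)) \
                if nfreexl > 0 else 0
            # hoisted per-species unbinding probabilities
            p1_5 = _pevent(P[IP_K5_K1], dt_l)
            p1_14m = _pevent(P[IP_K14_K1M], dt_l)
            p1_14d = _pevent(P[IP_K14_K1D], dt_l)
            p1_xl = _pevent(P[IP_XL_K1], dt_l)

            for il in range(NL):
                sp = lk_sp[il]
                st = lk_state[il]
                if st == LK_FREE:
                    want = False
                    if sp == SP_K5 and nb5 > 0:
                        nb5 -= 1
                        want = True
                    elif sp == SP_K14 and nb14 > 0:
                        nb14 -= 1
                        want = True
                    elif sp == SP_XL and nbxl > 0:
                        nbxl -= 1
                        want = True
                    if not want:
                        continue
                    rpick = _u01(rs) * total_len
                    acc = 0.0
                    jsel = M - 1
                    for j in range(M):
                        acc += mt_len[j]
                        if acc >= rpick:
                            jsel = j
                            break
                    arc = _u01(rs) * mt_len[jsel]
                    if sp == SP_K14:
                        if _u01(rs) < kon14m / (kon14m + kon14d):
                            lk_state[il] = LK_HEAD0
                            lk_mt[il, 0] = jsel
                            lk_pos[il, 0] = arc
                        else:
                            lk_state[il] = LK_HEAD1
                            lk_mt[il, 1] = jsel
                            lk_pos[il, 1] = arc
                    else:
                        lk_state[il] = LK_HEAD0
                        lk_mt[il, 0] = jsel
                        lk_pos[il, 0] = arc
                    lk_rate2[il] = 0.0
                    continue
                if st == LK_HEAD0 or st == LK_HEAD1:
                    h = 0 if st == LK_HEAD0 else 1
                    if sp == SP_K5:
                        p1 = p1_5
                    elif sp == SP_K14:
                        p1 = p1_14m if h == 0 else p1_14d
                    else:
                        p1 = p1_xl
                    if _u01(rs) < p1:
                        lk_state[il] = LK_FREE
                        continue
                    if lk_rate2[il] > 0.0 and \
                            _u01(rs) < _pevent(lk_rate2[il], dt_l):
                        tot, jsel, arc = _lk_stage2_enumerate(
                            P, sp, h, lk_mt[il, h], lk_pos[il, h],
                            mt_center, mt_axis, mt_len, True,
                            _u01(rs) * lk_rate2[il])
                        if jsel >= 0:
                            oh = 1 - h
                            lk_mt[il, oh] = jsel
                            lk_pos[il, oh] = arc
                            lk_state[il] = LK_BOTH
                            continue
                    j = lk_mt[il, h]
                    if sp == SP_K5:
                        lk_pos[il, h] += P[IP_K5_V0] * dt_l
                    elif sp == SP_K14 and h == 0:
                        lk_pos[il, h] += P[IP_K14_V0M] * dt_l
                    else:
                        # diffusive (non-motor) heads reflect at the ends
                        Dh = P[IP_K14_DD] if sp == SP_K14 else P[IP_XL_DSB]
                        pnew = lk_pos[il, h] + np.sqrt(2.0 * Dh * dt_l) \
                            * _randn(rs, gsp)
                        if pnew < 0.0:
                            pnew = -pnew
                        if pnew > mt_len[j]:
                            pnew = 2.0 * mt_len[j] - pnew
                        if pnew < 0.0:
                            pnew = 0.0
                        lk_pos[il, h] = pnew
                    if lk_pos[il, h] < 0.0 or lk_pos[il, h] > mt_len[j]:
                        lk_state[il] = LK_FREE
                    continue
                # doubly bound
                T = lk_tension[il]
                if sp == SP_K5:
                    k2a = P[IP_K5_K2]
                    k2b = P[IP_K5_K2]
                    xc = P[IP_K5_XC]
                elif sp == SP_K14:
                    k2a = P[IP_K14_K2M]
                    k2b = P[IP_K14_K2D]
                    xc = P[IP_K14_XC]
                else:
                    k2a = P[IP_XL_K2]
                    k2b = P[IP_XL_K2]
                    xc = P[IP_XL_XC]
                bell = _cexp(T * xc / kbt)
                off0 = _u01(rs) < _pevent(k2a * bell, dt_l)
                off1 = _u01(rs) < _pevent(k2b * bell, dt_l)
                if off0 and off1:
                    lk_state[il] = LK_FREE
                    continue
                if off0:
                    lk_state[il] = LK_HEAD1
                    lk_rate2[il] = 0.0
                    continue
                if off1:
                    lk_state[il] = LK_HEAD0
                    lk_rate2[il] = 0.0
                    continue
                i0 = lk_mt[il, 0]
                i1 = lk_mt[il, 1]
                if sp == SP_K5:
                    dd = (mt_axis[i0, 0] * mt_axis[i1, 0]
                          + mt_axis[i0, 1] * mt_axis[i1, 1]
                          + mt_axis[i0, 2] * mt_axis[i1, 2])
                    v0 = P[IP_K5_V0P] if dd > 0.0 else P[IP_K5_V0AP]
                    fs = P[IP_K5_FS]
                    for h in range(2):
                        axf = lk_ax0[il] if h == 0 else lk_ax1[il]
                        sgn = 1.0 if v0 >= 0.0 else -1.0
                        opp = -sgn * axf
                        if opp < 0.0:
                            opp = 0.0
                        fac = 1.0 - opp / fs
                        if fac < 0.0:
                            fac = 0.0
                        elif fac > 2.0:
                            fac = 2.0
                        lk_pos[il, h] += v0 * fac * dt_l
                elif sp == SP_K14:
                    opp = lk_ax0[il]  # minus-directed: +u load opposes
                    if opp < 0.0:
                        opp = 0.0
                    fac = 1.0 - opp / P[IP_K14_FS]
                    if fac < 0.0:
                        fac = 0.0
                    elif fac > 2.0:
                        fac = 2.0
                    lk_pos[il, 0] += P[IP_K14_V0M] * fac * dt_l
                    Dh = P[IP_K14_DD]
                    L1 = mt_len[lk_mt[il, 1]]
                    pnew = lk_pos[il, 1] + Dh / kbt * lk_ax1[il] * dt_l \
                        + np.sqrt(2.0 * Dh * dt_l) * _randn(rs, gsp)
                    if pnew < 0.0:
                        pnew = -pnew
                    if pnew > L1:
                        pnew = 2.0 * L1 - pnew
                    if pnew < 0.0:
                        pnew = 0.0
                    lk_pos[il, 1] = pnew
                else:
                    Dh = P[IP_XL_DDB]
                    dnoise = np.sqrt(2.0 * Dh * dt_l)
                    for h in range(2):
                        Lh = mt_len[lk_mt[il, h]]
                        axf = lk_ax0[il] if h == 0 else lk_ax1[il]
                        pnew = lk_pos[il, h] + Dh / kbt * axf * dt_l \
                            + dnoise * _randn(rs, gsp)
                        if pnew < 0.0:
                            pnew = -pnew
                        if pnew > Lh:
                            pnew = 2.0 * Lh - pnew
                        if pnew < 0.0:
                            pnew = 0.0
                        lk_pos[il, h] = pnew
                # motor heads running off an end detach that head
                for h in range(2):
                    j = lk_mt[il, h]
                    if lk_pos[il, h] < 0.0 or lk_pos[il, h] > mt_len[j]:
                        lk_state[il] = LK_HEAD1 - h  # surviving head
                        lk_rate2[il] = 0.0
                        break

            # ----- kMC: attachment factors --------------------------------
            dt_kmc = dt_l / nkmc
            for i in range(NAF):
                k = i // 3
                c = k // 2
                mode = af_mode[i]
                if mode == AF_UNBOUND:
                    if af_rate[i] <= 0.0:
                        continue
                    # Nkmc substeps, compounded into one draw
                    psub = _pevent(af_rate[i], dt_kmc)
                    ptot = 1.0 - (1.0 - psub) ** nkmc
                    if _u01(rs) >= ptot:
                        continue
                    slot = i % 3
                    off = (slot - 1) * P[IP_SITE_SEP]
                    sx = kc_pos[k, 0] + off * kc_t[k, 0]
                    sy = kc_pos[k, 1] + off * kc_t[k, 1]
                    sz = kc_pos[k, 2] + off * kc_t[k, 2]
                    tot, jsel, msel, arc = _af_bind_enumerate(
                        P, sx, sy, sz, kc_n[k, 0], kc_n[k, 1], kc_n[k, 2],
                        kc_occ[k], mt_center, mt_axis, mt_len, mt_state,
                        mt_tip_af, True, _u01(rs) * af_rate[i])
                    if jsel >= 0:
                        af_mode[i] = msel
                        af_mt[i] = jsel
                        af_pos[i] = arc
                        if msel == AF_ENDON:
                            mt_tip_af[jsel] = i
                            mt_grow_accum[jsel] = 0.0
                        af_rate[i] = 0.0
                    continue
                j = af_mt[i]
                if ana:
                    rate = P[IP_K_ANA]
                else:
                    th = af_theta[i]
                    occ = kc_occ[k]
                    if occ <= 1:
                        kap = P[IP_AF_KR1] if occ == 1 else P[IP_AF_KR0]
                    elif occ == 2:
                        kap = P[IP_AF_KR2]
                    else:
                        kap = P[IP_AF_KR3]
                    if mode == AF_ENDON:
                        if mt_state[j] == 1:
                            k0 = P[IP_K_TIP_A]
                            xc = P[IP_XC_TA]
                        else:
                            k0 = P[IP_K_TIP_D]
                            xc = P[IP_XC_TD]
                    else:
                        k0 = P[IP_K_SIDE]
                        xc = P[IP_XC_S]
                    rate = k0 * _cexp(af_tension[i] * xc / kbt) \
                        * _cexp(P[IP_CHI_C] * kap * th * th / (2.0 * kbt))
                    if P[IP_EC_MODE] > 0.5:
                        rate *= 2.0 ** (-interkc_tension[c] / P[IP_FEC0])
                    elif chrom_state[c] != CS_AMPHITELIC:
                        rate *= P[IP_S_ABK]
                psub = _pevent(rate, dt_kmc)
                ptot = 1.0 - (1.0 - psub) ** nkmc
                if _u01(rs) < ptot:
                    if mode == AF_ENDON:
                        mt_tip_af[j] = -1
                    af_mode[i] = AF_UNBOUND
                    af_mt[i] = -1
                    af_rate[i] = 0.0
                    continue
                L = mt_len[j]
                if mode == AF_LATERAL:
                    opp = -af_axial[i]
                    if opp < 0.0:
                        opp = 0.0
                    fac = 1.0 - opp / P[IP_AF_FS]
                    if fac < 0.0:
                        fac = 0.0
                    elif fac > 2.0:
                        fac = 2.0
                    af_pos[i] += P[IP_AF_V] * fac * dt_l \
                        + np.sqrt(2.0 * P[IP_D_SIDE] * dt_l) \
                        * _randn(rs, gsp)
                    if af_pos[i] < 0.0:
                        af_mode[i] = AF_UNBOUND
                        af_mt[i] = -1
                        af_rate[i] = 0.0
                        continue
                    if af_pos[i] >= L - tip_len:
                        if mt_tip_af[j] < 0:
                            af_mode[i] = AF_ENDON
                            af_pos[i] = L
                            mt_tip_af[j] = i
                            mt_grow_accum[j] = 0.0
                        else:
                            af_pos[i] = L - tip_len
                else:
                    af_pos[i] += np.sqrt(2.0 * P[IP_D_TIP] * dt_l) \
                        * _randn(rs, gsp)
                    if af_pos[i] > L:
                        af_pos[i] = L
                    elif af_pos[i] < L - tip_len:
                        af_pos[i] = L - tip_len

        # ----- refresh cached geometry-dependent binding rates ---------------
        if step % n_refresh == 0:
            for il in range(NL):
                if lk_state[il] == LK_HEAD0 or lk_state[il] == LK_HEAD1:
                    h = 0 if lk_state[il] == LK_HEAD0 else 1
                    tot, _j, _a = _lk_stage2_enumerate(
                        P, lk_sp[il], h, lk_mt[il, h], lk_pos[il, h],
                        mt_center, mt_axis, mt_len, False, 0.0)
                    lk_rate2[il] = tot
                else:
                    lk_rate2[il] = 0.0
            for i in range(NAF):
                if af_mode[i] == AF_UNBOUND:
                    k = i // 3
                    slot = i % 3
                    off = (slot - 1) * P[IP_SITE_SEP]
                    sx = kc_pos[k, 0] + off * kc_t[k, 0]
                    sy = kc_pos[k, 1] + off * kc_t[k, 1]
                    sz = kc_pos[k, 2] + off * kc_t[k, 2]
                    tot, _j, _m, _a = _af_bind_enumerate(
                        P, sx, sy, sz, kc_n[k, 0], kc_n[k, 1], kc_n[k, 2],
                        kc_occ[k], mt_center, mt_axis, mt_len, mt_state,
                        mt_tip_af, False, 0.0)
                    af_rate[i] = tot
                else:
                    af_rate[i] = 0.0

    return STATUS_OK, isamp
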