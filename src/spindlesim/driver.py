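"""Simulation driver: initialization, the main loop, and trajectories.

The initial condition mimics early mitosis: two side-by-side SPBs on the
nuclear envelope separated by the bridge distance, 14 short growing MTs
per SPB, three chromosomes proximal to the SPBs with the pole-facing
sister oriented toward them (monotelic-compatible), and all motors,
crosslinkers, and attachment factors unbound.

``run(params, seed)`` advances the compiled kernel for the configured
duration and returns a :class:`Trajectory` of sampled observables.
Identical ``(params, seed)`` reproduce identical trajectories on one
platform: a single RNG stream is used and every stochastic draw is
ordered by entity index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine
from .params import ModelParams


class SimulationInstability(RuntimeError):
    """Raised when the integrator produces NaNs; carries the partial state."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class SimulationState:
    """All mutable degrees of freedom at one instant (internal units, nm)."""

    spb_pos: np.ndarray          # (2, 3)
    spb_ang: np.ndarray          # (2,)
    anchor_local: np.ndarray     # (2, n_sites, 2)
    mt_center: np.ndarray        # (M, 3)
    mt_axis: np.ndarray          # (M, 3)
    mt_len: np.ndarray           # (M,)
    mt_state: np.ndarray         # (M,) 1 growing / 0 shrinking
    mt_spb: np.ndarray           # (M,)
    mt_site: np.ndarray          # (M,)
    mt_grow_accum: np.ndarray    # (M,)
    mt_tip_af: np.ndarray        # (M,) index of end-on AF or -1
    kc_pos: np.ndarray           # (K, 3)
    kc_n: np.ndarray             # (K, 3) outward plate normals
    kc_t: np.ndarray             # (K, 3) plate long axes
    af_mode: np.ndarray          # (3K,)
    af_mt: np.ndarray            # (3K,)
    af_pos: np.ndarray           # (3K,)
    lk_sp: np.ndarray            # (N,) species id
    lk_state: np.ndarray         # (N,)
    lk_mt: np.ndarray            # (N, 2)
    lk_pos: np.ndarray           # (N, 2)
    sac_state: np.ndarray        # (2,) [cumulative biorientation s, triggered]

    @property
    def n_mts(self) -> int:
        return self.mt_len.shape[0]

    @property
    def n_kinetochores(self) -> int:
        return self.kc_pos.shape[0]

    def spindle_length_nm(self) -> float:
        return float(np.linalg.norm(self.spb_pos[1] - self.spb_pos[0]))


@dataclass
class Trajectory:
    """Sampled observable series of one run (times in s, lengths in nm)."""

    times_s: np.ndarray
    spb_positions_nm: np.ndarray       # (S, 2, 3)
    kc_positions_nm: np.ndarray        # (S, K, 3)
    spindle_length_nm: np.ndarray      # (S,)
    interkc_nm: np.ndarray             # (S, NC)
    chromosome_states: np.ndarray      # (S, NC) engine CS_* codes
    class_forces_pn: np.ndarray        # (S, 4) k5, k14, xl, chromosome
    bound_counts: np.ndarray           # (S, 3, 3) species x (free, one, two)
    af_mt: np.ndarray                  # (S, 3K) bound MT id or -1
    af_mode: np.ndarray                # (S, 3K)
    mean_mt_length_nm: np.ndarray      # (S,)
    cumulative_biorientation_s: np.ndarray  # (S,)
    anaphase_flag: np.ndarray          # (S,)
    params: ModelParams = None
    seed: int = 0

    @property
    def times_min(self) -> np.ndarray:
        return self.times_s / 60.0

    @property
    def spindle_length_um(self) -> np.ndarray:
        return self.spindle_length_nm / 1000.0

    def spb_kc_distance_um(self) -> np.ndarray:
        """Distance of every kinetochore to its nearer SPB, (S, K), um."""
        d0 = np.linalg.norm(
            self.kc_positions_nm - self.spb_positions_nm[:, 0:1, :], axis=2)
        d1 = np.linalg.norm(
            self.kc_positions_nm - self.spb_positions_nm[:, 1:2, :], axis=2)
        return np.minimum(d0, d1) / 1000.0

    def all_bioriented(self) -> np.ndarray:
        """Boolean series: every chromosome simultaneously amphitelic."""
        return np.all(self.chromosome_states == engine.CS_AMPHITELIC, axis=1)

    def save_hdf5(self, path) -> None:
        import h5py
        import yaml as _yaml
        with h5py.File(path, "w") as fh:
            for name in ("times_s", "spb_positions_nm", "kc_positions_nm",
                         "spindle_length_nm", "interkc_nm", "chromosome_states",
                         "class_forces_pn", "bound_counts", "af_mt", "af_mode",
                         "mean_mt_length_nm", "cumulative_biorientation_s",
                         "anaphase_flag"):
                d = fh.create_dataset(name, data=getattr(self, name))
                if name.endswith("_nm"):
                    d.attrs["units"] = "nm"
                elif name.endswith("_s"):
                    d.attrs["units"] = "s"
                elif name.endswith("_pn"):
                    d.attrs["units"] = "pN"
            fh.attrs["seed"] = self.seed
            fh.attrs["config_yaml"] = _yaml.safe_dump(self.params.to_dict())

    @classmethod
    def load_hdf5(cls, path) -> "Trajectory":
        import h5py
        import yaml as _yaml
        with h5py.File(path, "r") as fh:
            kw = {name: fh[name][...] for name in
                  ("times_s", "spb_positions_nm", "kc_positions_nm",
                   "spindle_length_nm", "interkc_nm", "chromosome_states",
                   "class_forces_pn", "bound_counts", "af_mt", "af_mode",
                   "mean_mt_length_nm", "cumulative_biorientation_s",
                   "anaphase_flag")}
            seed = int(fh.attrs["seed"])
            params = ModelParams.from_dict(
                _yaml.safe_load(fh.attrs["config_yaml"]))
        return cls(params=params, seed=seed, **kw)


def _tangent_frame(rhat: np.ndarray, ang: float):
    """Matches the engine's anchor frame construction."""
    e1 = np.array([-rhat[1], rhat[0], 0.0])
    n = np.linalg.norm(e1)
    if n < 1e-8:
        e1 = np.array([1.0, 0.0, 0.0])
    else:
        e1 /= n
    e2 = np.cross(rhat, e1)
    c, s = np.cos(ang), np.sin(ang)
    return c * e1 + s * e2, -s * e1 + c * e2


def initialize_state(params: ModelParams, rng: np.random.Generator) -> SimulationState:
    """Build the early-mitosis initial condition.

    Chromosome placement is rejection-sampled so that no steric pair
    overlaps at t = 0.
    """
    params.validate()
    R = params.simulation.nucleus_radius_um * 1000.0
    bridge = params.spb.bridge_size_nm
    n_sites = params.spb.n_nucleation_sites
    l_min = params.microtubule.min_length_nm
    r0 = params.spb.tether_rest_length_nm
    nc = params.chromosome.count
    K = 2 * nc

    # SPBs side by side on the sphere, chord separation = bridge size
    sth = 0.5 * bridge / R
    cth = np.sqrt(1.0 - sth * sth)
    spb_pos = np.array([[R * sth, 0.0, R * cth],
                        [-R * sth, 0.0, R * cth]])
    spb_ang = np.zeros(2)

    # anchor sites scattered on each SPB face
    anchor_local = np.zeros((2, n_sites, 2))
    r_face = 0.45 * params.spb.diameter_um * 1000.0
    for ispb in range(2):
        rho = r_face * np.sqrt(rng.random(n_sites))
        phi = 2.0 * np.pi * rng.random(n_sites)
        anchor_local[ispb, :, 0] = rho * np.cos(phi)
        anchor_local[ispb, :, 1] = rho * np.sin(phi)

    # MTs: minus ends at tether rest distance inward of their anchors
    M = 2 * n_sites
    mt_center = np.zeros((M, 3))
    mt_axis = np.zeros((M, 3))
    mt_len = np.full(M, l_min)
    mt_state = np.ones(M, dtype=np.int64)
    mt_spb = np.zeros(M, dtype=np.int64)
    mt_site = np.zeros(M, dtype=np.int64)
    i = 0
    for ispb in range(2):
        rhat = spb_pos[ispb] / np.linalg.norm(spb_pos[ispb])
        nin = -rhat
        e1, e2 = _tangent_frame(rhat, 0.0)
        for s in range(n_sites):
            anchor = (spb_pos[ispb] + anchor_local[ispb, s, 0] * e1
                      + anchor_local[ispb, s, 1] * e2)
            # broad splay: uniform over the inward-facing hemisphere
            while True:
                a = rng.standard_normal(3)
                a /= np.linalg.norm(a)
                if np.dot(a, nin) > 0.05:
                    break
            minus = anchor + r0 * nin
            mt_center[i] = minus + 0.5 * l_min * a
            mt_axis[i] = a
            mt_spb[i] = ispb
            mt_site[i] = s
            i += 1

    # chromosomes proximal to the SPBs, pole-facing sister toward them
    spb_mid = 0.5 * (spb_pos[0] + spb_pos[1])
    inward = -spb_mid / np.linalg.norm(spb_mid)
    rc0 = params.chromosome.inter_kc_rest_nm
    kc_pos = np.zeros((K, 3))
    kc_n = np.zeros((K, 3))
    kc_t = np.zeros((K, 3))
    def _overlaps_mts(center, axis_u, pa, pb, t_axis):
        """Steric check of the candidate chromosome against all MTs."""
        from ._formulas import closest_points_segments
        half_ch = 0.5 * max(params.chromosome.chromatin_length_nm
                            - params.chromosome.chromatin_diameter_nm, 0.0)
        sig_ch = 0.5 * (params.chromosome.chromatin_diameter_nm
                        + params.microtubule.diameter_nm)
        half_kc = 0.5 * (params.chromosome.kc_length_nm
                         - params.chromosome.kc_width_nm)
        sig_kc = 0.5 * (params.chromosome.kc_width_nm
                        + params.microtubule.diameter_nm)
        for i in range(M):
            m0 = mt_center[i] - 0.5 * mt_len[i] * mt_axis[i]
            m1 = mt_center[i] + 0.5 * mt_len[i] * mt_axis[i]
            _, _, d, _, _ = closest_points_segments(
                center - half_ch * axis_u, center + half_ch * axis_u, m0, m1)
            if d < sig_ch + 5.0:
                return True
            for kc_center in (pa, pb):
                _, _, d, _, _ = closest_points_segments(
                    kc_center - half_kc * t_axis, kc_center + half_kc * t_axis,
                    m0, m1)
                if d < sig_kc + 5.0:
                    return True
        return False

    for c in range(nc):
        for _attempt in range(500):
            dist = 150.0 + 250.0 * rng.random()
            perp = rng.standard_normal(3)
            perp -= np.dot(perp, inward) * inward
            perp /= np.linalg.norm(perp)
            center = spb_mid + dist * inward + 250.0 * rng.random() * perp
            if np.linalg.norm(center) > R - 150.0:
                continue
            u = center - spb_mid
            u /= np.linalg.norm(u)
            pa = center - 0.5 * rc0 * u
            pb = center + 0.5 * rc0 * u
            # keep chromosomes apart from each other
            ok = True
            for cprev in range(c):
                if np.linalg.norm(center - 0.5 * (kc_pos[2 * cprev]
                                                  + kc_pos[2 * cprev + 1])) < 250.0:
                    ok = False
            if not ok:
                continue
            t = np.cross(u, rng.standard_normal(3))
            t /= np.linalg.norm(t)
            if _overlaps_mts(center, u, pa, pb, t):
                continue
            kc_pos[2 * c] = pa
            kc_n[2 * c] = -u        # faces the poles
            kc_t[2 * c] = t
            kc_pos[2 * c + 1] = pb
            kc_n[2 * c + 1] = u
            kc_t[2 * c + 1] = t
            break
        else:
            raise RuntimeError("could not place chromosomes without overlap")

    naf = 3 * K
    af_mode = np.zeros(naf, dtype=np.int64)
    af_mt = np.full(naf, -1, dtype=np.int64)
    af_pos = np.zeros(naf)
    mt_tip_af = np.full(M, -1, dtype=np.int64)

    n5 = params.kinesin5.number
    n14 = params.kinesin14.number
    nxl = params.crosslinker.number
    NL = n5 + n14 + nxl
    lk_sp = np.concatenate([
        np.full(n5, engine.SP_K5, dtype=np.int64),
        np.full(n14, engine.SP_K14, dtype=np.int64),
        np.full(nxl, engine.SP_XL, dtype=np.int64)])
    lk_state = np.zeros(NL, dtype=np.int64)
    lk_mt = np.full((NL, 2), -1, dtype=np.int64)
    lk_pos = np.zeros((NL, 2))

    return SimulationState(
        spb_pos=spb_pos, spb_ang=spb_ang, anchor_local=anchor_local,
        mt_center=mt_center, mt_axis=mt_axis, mt_len=mt_len,
        mt_state=mt_state, mt_spb=mt_spb, mt_site=mt_site,
        mt_grow_accum=np.zeros(M), mt_tip_af=mt_tip_af,
        kc_pos=kc_pos, kc_n=kc_n, kc_t=kc_t,
        af_mode=af_mode, af_mt=af_mt, af_pos=af_pos,
        lk_sp=lk_sp, lk_state=lk_state, lk_mt=lk_mt, lk_pos=lk_pos,
        sac_state=np.zeros(2))


def run(params: ModelParams, seed: int,
        state: SimulationState | None = None,
        duration_s: float | None = None) -> Trajectory:
    """Run a full simulation and return the sampled trajectory.

    ``seed`` drives both the initial-condition generator and the kernel's
    kinetic Monte Carlo / Brownian noise stream (derived deterministically).
    A pre-built ``state`` may be supplied to continue or to run customized
    initial conditions.
    """
    params.validate()
    dt = params.simulation.time_step_s
    dur = duration_s if duration_s is not None else params.simulation.duration_s
    n_steps = max(1, int(round(dur / dt)))
    stride = max(1, int(round(params.simulation.sample_interval_s / dt)))
    n_samples = (n_steps - 1) // stride + 1

    if state is None:
        state = initialize_state(params, np.random.default_rng(seed))
    P = params.pack()
    kernel_seed = (seed * 2654435761 + 12345) % (2 ** 31 - 1)

    K = state.kc_pos.shape[0]
    nc = K // 2
    naf = 3 * K
    out = dict(
        out_t=np.zeros(n_samples),
        out_spb=np.zeros((n_samples, 2, 3)),
        out_kc=np.zeros((n_samples, K, 3)),
        out_spindle=np.zeros(n_samples),
        out_interkc=np.zeros((n_samples, nc)),
        out_chrom_state=np.zeros((n_samples, nc), dtype=np.int64),
        out_class_force=np.zeros((n_samples, 4)),
        out_bound=np.zeros((n_samples, 3, 3), dtype=np.int64),
        out_af_mt=np.full((n_samples, naf), -1, dtype=np.int64),
        out_af_mode=np.zeros((n_samples, naf), dtype=np.int64),
        out_mt_len=np.zeros(n_samples),
        out_bio=np.zeros(n_samples),
        out_ana=np.zeros(n_samples),
    )
    status, nsamp = engine.run_kernel(
        P, kernel_seed, n_steps, stride,
        state.spb_pos, state.spb_ang, state.anchor_local,
        state.mt_center, state.mt_axis, state.mt_len, state.mt_state,
        state.mt_spb, state.mt_site, state.mt_grow_accum, state.mt_tip_af,
        state.kc_pos, state.kc_n, state.kc_t,
        state.af_mode, state.af_mt, state.af_pos,
        state.lk_sp, state.lk_state, state.lk_mt, state.lk_pos,
        state.sac_state,
        out["out_t"], out["out_spb"], out["out_kc"], out["out_spindle"],
        out["out_interkc"], out["out_chrom_state"], out["out_class_force"],
        out["out_bound"], out["out_af_mt"], out["out_af_mode"],
        out["out_mt_len"], out["out_bio"], out["out_ana"])

    traj = Trajectory(
        times_s=out["out_t"][:nsamp],
        spb_positions_nm=out["out_spb"][:nsamp],
        kc_positions_nm=out["out_kc"][:nsamp],
        spindle_length_nm=out["out_spindle"][:nsamp],
        interkc_nm=out["out_interkc"][:nsamp],
        chromosome_states=out["out_chrom_state"][:nsamp],
        class_forces_pn=out["out_class_force"][:nsamp],
        bound_counts=out["out_bound"][:nsamp],
        af_mt=out["out_af_mt"][:nsamp],
        af_mode=out["out_af_mode"][:nsamp],
        mean_mt_length_nm=out["out_mt_len"][:nsamp],
        cumulative_biorientation_s=out["out_bio"][:nsamp],
        anaphase_flag=out["out_ana"][:nsamp],
        params=params, seed=seed)
    if status == engine.STATUS_NAN:
        raise SimulationInstability(
            "numerical instability (NaN) during integration; partial "
            "trajectory attached", trajectory=traj)
    return traj
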