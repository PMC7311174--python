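"""Species-specific behavior of kinesin-5, kinesin-14, and passive
crosslinkers.

Kinesin-5 is context-bidirectional: minus-directed when singly bound or
crosslinking polar-aligned MTs, plus-directed (sliding poles apart) on
antiparallel pairs.  Kinesin-14 walks one head toward minus ends while its
passive head diffuses.  Passive crosslinkers prefer antiparallel overlaps
and flag stabilization of MT dynamics when bound near a plus end
(CLASP-mimic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import _formulas as f
from .params import KBT_PN_NM, Kinesin14Params, Kinesin5Params


class Stage(Enum):
    FREE = 0
    ONE_HEAD = 1
    TWO_HEADS = 2


@dataclass
class LinkerRecord:
    """One motor or crosslinker molecule."""

    species: str  # "kinesin5" | "kinesin14" | "crosslinker"
    stage: Stage = Stage.FREE
    mt: tuple = (-1, -1)  # host filament ids (head 0, head 1)
    pos: np.ndarray = field(default_factory=lambda: np.zeros(2))  # arc nm

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)


def pair_alignment(axis_a: np.ndarray, axis_b: np.ndarray) -> str:
    """'polar' for positive axis dot product, else 'antipolar'.

    A zero dot product (measure-zero) breaks toward antipolar.
    """
    return "polar" if float(np.dot(axis_a, axis_b)) > 0.0 else "antipolar"


def kinesin5_velocity(stage: Stage, alignment: str | None,
                      parallel_force: float = 0.0,
                      p: Kinesin5Params | None = None) -> float:
    """Context-dependent per-head kinesin-5 velocity (nm/s, + toward plus end).

    Singly bound: fast minus-directed (-100 nm/s); crosslinking parallel
    MTs: slow minus-directed (-50 nm/s); crosslinking antiparallel MTs:
    plus-directed (+8 nm/s per head, i.e. 16 nm/s relative sliding).  The
    unloaded speed is then scaled by the linear force-velocity relation
    with ``parallel_force`` the load component opposing the motion.
    """
    p = p or Kinesin5Params()
    if stage == Stage.ONE_HEAD:
        v0 = p.v_single_nm_s
    elif stage == Stage.TWO_HEADS:
        if alignment == "polar":
            v0 = p.v_polar_nm_s
        else:
            v0 = p.v_antipolar_nm_s
    else:
        return 0.0
    return f.force_velocity(v0, parallel_force, p.stall_force_pn)


def kinesin14_update(record: LinkerRecord, opposing_forces, dt: float,
                     rng: np.random.Generator,
                     p: Kinesin14Params | None = None) -> np.ndarray:
    """Advance the two kinesin-14 heads along their filaments.

    Head 0 is the motor head: it walks at -50 nm/s toward the minus end,
    scaled by force-velocity.  Head 1 is the passive head: it diffuses
    with Dd and drifts down the tether-force gradient (mobility Dd/kBT).
    ``opposing_forces`` gives, per head, the axial load opposing motion
    (motor head) / the axial tether force in the plus direction (passive
    head).  Returns the new arc positions (does not handle unbinding).
    """
    p = p or Kinesin14Params()
    fo = np.asarray(opposing_forces, dtype=float)
    new = record.pos.copy()
    if record.stage in (Stage.ONE_HEAD, Stage.TWO_HEADS):
        new[0] += f.force_velocity(p.v_motor_nm_s, fo[0], p.stall_force_pn) * dt
    if record.stage == Stage.TWO_HEADS:
        dd = p.d_passive_um2_s * 1.0e6  # nm^2/s
        drift = dd / KBT_PN_NM * fo[1] * dt
        new[1] += drift + np.sqrt(2.0 * dd * dt) * rng.standard_normal()
    return new


def crosslinker_stage2_affinity(axis_a: np.ndarray, axis_b: np.ndarray,
                                parallel_affinity: float = 0.33) -> float:
    """Multiplicative second-head binding factor for a candidate MT pair.

    Antiparallel pairs (negative axis dot product) bind at full rate;
    parallel pairs are penalized by the parallel-to-antiparallel affinity
    ratio.
    """
    return 1.0 if float(np.dot(axis_a, axis_b)) < 0.0 else parallel_affinity


def crosslink_stabilization_query(mt_id: int, mt_length: float,
                                  records, stabilization_length: float = 16.0) -> bool:
    """True iff a doubly bound crosslinker occupies this MT within the
    stabilization length of its plus end (gates the stabilized DI set)."""
    for rec in records:
        if rec.species != "crosslinker" or rec.stage != Stage.TWO_HEADS:
            continue
        for head in (0, 1):
            if rec.mt[head] == mt_id and rec.pos[head] >= mt_length - stabilization_length:
                return True
    return False
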