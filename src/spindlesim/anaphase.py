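"""Checkpoint-like anaphase trigger and anaphase-A rules.

Anaphase fires once the cumulative time during which *all* chromosomes are
simultaneously bioriented reaches tau_SAC (no reset on transient loss of
biorientation; the trigger latches).  After the trigger: the
interkinetochore springs are severed, all attachment-factor detachment
rates drop to the (tiny) anaphase rate, and kinetochore-attached MTs
switch to persistent depolymerization, carrying chromosomes poleward.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import AnaphaseParams, ModelParams


@dataclass
class SACTimer:
    """Accumulates simultaneous-biorientation time and latches the trigger."""

    tau_sac_s: float = 4.45 * 60.0
    cumulative_s: float = 0.0
    triggered: bool = False

    def update(self, all_bioriented: bool, dt: float) -> bool:
        """Advance by dt; time accumulates only while all chromosomes are
        amphitelic.  Returns the (latched) trigger state."""
        if not self.triggered and all_bioriented:
            self.cumulative_s += dt
        if self.cumulative_s >= self.tau_sac_s:
            self.triggered = True
        return self.triggered


def check_sac(cumulative_biorientation_min: float,
              tau_sac_min: float = 4.45) -> bool:
    """True once the integrated simultaneous-biorientation time reaches
    tau_SAC (latching is the caller's responsibility via SACTimer)."""
    return cumulative_biorientation_min >= tau_sac_min


def apply_anaphase(params: ModelParams) -> ModelParams:
    """Return the post-trigger parameter transformation.

    Severs the chromatin spring between sisters (all interkinetochore
    stiffnesses to zero), replaces every attachment-factor detachment rate
    by the anaphase rate (attachment lifetime 1/k ~ hours, i.e. effectively
    permanent on segregation timescales), and marks anaphase active so the
    engine depolymerizes kinetochore-attached MTs at the anaphase speed.
    The caller must only invoke this after the trigger has fired.
    """
    a: AnaphaseParams = params.anaphase
    params.chromosome.inter_kc_spring_pn_um = 0.0
    params.chromosome.inter_kc_rot_pn_nm = 0.0
    params.chromosome.inter_kc_align_pn_nm = 0.0
    k = a.attachment_rate_s
    params.attachment.k_side_s = k
    params.attachment.k_tip_assembling_s = k
    params.attachment.k_tip_disassembling_s = k
    params.attachment.misaligned_destabilization = 1.0
    return params
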