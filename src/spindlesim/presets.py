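"""Named model variants.

Each preset is a small set of documented overrides on the reference
parameter set.  The reference model itself is the empty override set.
"""

from __future__ import annotations

from .params import KBT_PN_NM, ConfigError, ModelParams

# 100 kBT angular stiffness: attachment restricted to a narrow cone.
_RESTRICTED = 100.0 * KBT_PN_NM

PRESETS: dict[str, dict] = {
    # Fitted reference model (all table defaults).
    "reference": {},
    # Kinesin-5 deletion: SPBs should fail to separate.
    "no_kinesin5": {"kinesin5.number": 0},
    # CLASP-like crosslink-mediated MT stabilization turned off: spindles
    # fail to elongate past ~1 um.
    "no_stabilization": {"microtubule.stabilization_enabled": False},
    # Ase1-like crosslinker deletion.
    "no_crosslinker": {"crosslinker.number": 0},
    # All attachment events highly restricted in angle (100 kBT): transient
    # attachments, low chromosome inward force, small length fluctuations.
    "restricted_attachment": {
        "attachment.angular_stiffness_pn_nm": (_RESTRICTED, _RESTRICTED,
                                               _RESTRICTED, _RESTRICTED),
    },
    # Force-dependent rescue weakened by doubling the rescue force factor:
    # long attachment lifetimes and large spindle length fluctuations.
    "weak_rescue": {"attachment.f_rescue_pn": 12.8},
    # Interkinetochore-tension error correction instead of the rule-based
    # misaligned destabilization.
    "force_ec": {
        "error_correction.mode": "force",
        "chromosome.inter_kc_rot_pn_nm": 925.0,
        "chromosome.inter_kc_align_pn_nm": 925.0,
        "attachment.angular_factor": 0.08,
        "attachment.side_concentration_inv_nm": 0.32,
        "kinesin5.number": 200,
    },
    # Deformable nuclear envelope: SPBs move radially against a saturating
    # wall force instead of being pinned to the sphere.
    "soft_envelope": {"envelope.mode": "soft"},
    # Kinesin-14 given the same force sensitivity of unbinding as kinesin-5.
    "kinesin14_xc_adjusted": {"kinesin14.xc_nm": 1.5},
    # Anaphase rules armed (checkpoint trigger, spring severing, attachment
    # stabilization, poleward depolymerization).
    "anaphase": {"anaphase.enabled": True},
}


def get_preset(name: str, base: ModelParams | None = None) -> ModelParams:
    """Return a validated parameter set for a named model variant."""
    if name not in PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}")
    params = base if base is not None else ModelParams()
    return params.apply_overrides(dict(PRESETS[name]))
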