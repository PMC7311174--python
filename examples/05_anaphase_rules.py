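"""Checkpoint trigger and anaphase-A rule set.

Demonstrates the spindle-assembly-checkpoint-like timer (cumulative
simultaneous-biorientation time, latching at 4.45 min) and the parameter
transformation applied at anaphase onset, without running a full
simulation.
"""

from spindlesim.anaphase import SACTimer, apply_anaphase
from spindlesim.params import ModelParams

timer = SACTimer()
print(f"trigger threshold: {timer.tau_sac_s / 60:.2f} min of cumulative "
      "simultaneous biorientation (no reset on transient loss)")

# four minutes bioriented, a 30 s loss, then 30 s more
timer.update(True, 4 * 60.0)
timer.update(False, 30.0)
print(f"after 4.0 min bioriented + 0.5 min loss: cumulative "
      f"{timer.cumulative_s / 60:.2f} min, triggered={timer.triggered}")
timer.update(True, 30.0)
print(f"after 0.5 min more: cumulative {timer.cumulative_s / 60:.2f} min, "
      f"triggered={timer.triggered} (latched)")

params = apply_anaphase(ModelParams())
print("\nanaphase rule set:")
print(f"  interkinetochore springs severed -> "
      f"{params.chromosome.inter_kc_spring_pn_um} pN/um")
print(f"  attachment detachment rate -> {params.attachment.k_side_s:.0e} /s "
      f"(lifetime {1 / params.attachment.k_side_s / 60:.0f} min, effectively "
      "permanent)")
print(f"  kinetochore MTs depolymerize at "
      f"{params.anaphase.depoly_speed_um_min} um/min, carrying chromosomes "
      "poleward")
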