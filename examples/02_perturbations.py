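"""Genetic-perturbation presets: kinesin-5 deletion and loss of
crosslink-mediated MT stabilization.

Both perturbations abolish bipolar spindle assembly: without kinesin-5
there is no outward sliding force, and without the CLASP-like
stabilization of crosslinked MTs the antiparallel overlaps collapse.
The printed maximum spindle lengths show the contrast with the
reference model.
"""

import spindlesim as ss

DURATION_S = 90.0

for preset in ("reference", "no_kinesin5", "no_stabilization"):
    params = ss.get_preset(preset)
    params.simulation.duration_s = DURATION_S
    traj = ss.run(params, seed=2)
    print(f"{preset:18s} max spindle length {traj.spindle_length_um.max():.3f} um"
          f"  (final {traj.spindle_length_um[-1]:.3f} um)")

print("\nWithout kinesin-5 there is no outward sliding force and without "
      "crosslink stabilization antiparallel overlaps collapse; both perturbed "
      "models stay near the initial 0.075 um bridge separation.  At this "
      "scaled-down horizon the reference model's pole separation is also "
      "modest; the published study conditions are tens of simulated minutes.")
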