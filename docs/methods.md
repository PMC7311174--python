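# Model and methods

`spindlesim` is a three-dimensional Brownian-dynamics (BD) / kinetic Monte
Carlo (kMC) model of mitotic spindle assembly, chromosome biorientation,
and anaphase-A segregation in a fission-yeast-sized nucleus.  This note
documents the model, its assumptions, the tunable parameters, the
numerical choices, and the limits of what the test suite demonstrates.

## Physical model

**Geometry.** The nucleus is a sphere of radius R = 1.375 µm.  Two
spindle-pole bodies (SPBs, diameter 162.5 nm) are embedded in the nuclear
envelope.  In the default *rigid* envelope the SPBs are constrained to
the sphere surface (tangential dynamics, exact radial projection each
step); the *soft* envelope variant lets them move radially against a
saturating deformation force (17 pN asymptotic for SPBs, 2.5 pN for MT
tips, crossover over the 87.7 nm membrane-tube radius; realized as
F = f_wall·tanh(Δr/ℓ_tube), which vanishes at the preferred radius and
saturates — the published tables fix only the asymptote and tube radius,
so the crossover shape is this package's choice).

**Microtubules.** Each SPB nucleates 14 MTs, rigid spherocylinders of
diameter 25 nm whose minus ends are tethered by springs (K₀ =
0.6625 pN/nm, rest length 50 nm) to anchor points scattered on the SPB
face.  Plus ends undergo dynamic instability: growth 4.1 µm/min,
shrinkage 6.7 µm/min, catastrophe 3.994 min⁻¹, rescue 0.157 min⁻¹, with
a 75 nm minimum length at which a shrinking MT is reset to growth.
Compressive axial load F at the tip multiplies the catastrophe rate by
exp(α_c F) with α_c = 0.5 pN⁻¹.  A doubly bound crosslinker within 16 nm
of a plus end switches that MT to the stabilized parameter set
(×1.54 growth, ×0.094 shrinkage, ×0.098 catastrophe, ×18 rescue), the
CLASP-recruitment mimic.  End-on kinetochore attachment makes all four
parameters force-dependent through exponential force factors
(8.4, −3.0, −2.3, +6.4 pN), with growth capped at 30 µm/min; the
stabilization multipliers and attachment force factors compose
multiplicatively when both apply.

**Motors and crosslinkers.** Three species populate the nucleus:
kinesin-5 (174 copies; bidirectional: −100 nm/s singly bound, −50 nm/s
crosslinking parallel MTs, +8 nm/s per head on antiparallel pairs, so
antiparallel sliding separates the poles), kinesin-14 (230 copies; one
motor head walking at −50 nm/s, one diffusive head, D = 0.1 µm²/s), and
the passive antiparallel-preferring crosslinker (657 copies; parallel
binding penalized ×0.33).  Binding is microscopically reversible:
solution→one-head rates are K_a·k₁·[sites] against the zero-force
off-rate k₁; one→two-head rates integrate c₂·k₂·exp(−U/k_BT) over
candidate filament segments against the per-head off-rate k₂, so a
frozen two-head chain equilibrates to Boltzmann occupancies (tested by a
χ² detailed-balance check).  Unbinding under tether tension F follows
Bell's law exp(F·x_c/k_BT); motor stepping follows the linear
force-velocity relation v₀(1 − f/F_s) with the (1 − f/F_s) factor clamped
to [0, 2].

**Chromosomes.** Each of the three chromosomes is a pair of sister
kinetochores — 150×50 nm plates with three attachment factors (AFs)
spaced 40 nm along the plate — joined by a linear spring (39 pN/µm, rest
100 nm) and angular springs (1850 pN·nm/rad) that keep the plates
back-to-back and mutually aligned.  The pericentric chromatin is a
200×75 nm spherocylinder slaved to the sister pair (centered at the
sister midpoint, axis along the sister–sister axis); it repels MTs softly
(quadratic overlap energy, 1 pN·nm amplitude), so MTs can pass through
chromatin at an energy cost while kinetochore plates are hard.

**Attachment model.** AFs bind laterally or end-on (25 nm tip region,
at most one end-on AF per tip), with tip/side concentrations and rates
that favor end-on attachment, a 54 nm / 0.088 pN/nm tether, a
plus-directed kinetochore motor (50 nm/s, 5 pN stall), and tip tracking:
during shrinkage the AF moves with the tip; during growth each 8 nm of
added lattice is a tracking opportunity passed with probability 0.25,
else the AF converts to lateral.  Three mechanisms produce robust
biorientation:

1. *Progressive restriction*: the angular spring constant gating new
   attachments (and torquing bound ones) grows with site occupancy,
   4.1 → 41 → 410 → 410 pN·nm, so the first MT binds permissively and
   later ones only near the plate normal.
2. *Misaligned destabilization*: every attachment of a non-amphitelic
   chromosome detaches 70× faster (Aurora-B mimic).  The alternative
   force-dependent error-correction variant instead multiplies all
   detachment rates of a sister pair by 2^(−F_interKC/1.67 pN).
3. *Force-dependent attachment*: end-on detachment from a depolymerizing
   tip has x_c = −3.9 nm — a catch bond whose lifetime grows with load —
   which maintains biorientation while kinetochore MTs shorten under
   interkinetochore tension.

**Anaphase.** Cumulative time with all chromosomes simultaneously
amphitelic is integrated (no reset on loss); at 4.45 min the trigger
latches: interkinetochore springs are severed, every AF detachment rate
drops to 7×10⁻⁵ s⁻¹ (lifetime ≈ 238 min, effectively permanent), and
kinetochore-attached MTs depolymerize persistently at 2.2 µm/min,
carrying chromosomes poleward.  Unattached MTs keep normal dynamics.

## Numerical scheme

The integration order per time step (δt = 8.9×10⁻⁶ s) is: force/torque
accumulation → BD updates (MTs as rigid rods with slender-body drags;
kinetochore plates with the tabulated drags; SPBs on-sphere) → constraint
projection → dynamic instability → kMC state changes.  Specific choices:

- **Units**: pN, nm, s internally; k_BT = 4.114 pN·nm.  Config fields
  carry the unit of the published tables in their names and are
  converted once.
- **Steric interactions**: WCA (cut-and-shifted Lennard-Jones) with
  cutoff 2^(1/6)·(sum of radii) and ε = 1 k_BT — a stiff, continuous
  stand-in for a hard core that keeps BD stable; forces are clamped at
  200 pN.  The rigid envelope acts on MT tips as a stiff linear inward
  wall; its axial component feeds the catastrophe model.
- **Viscosity**: the published tables fix the SPB and kinetochore drags
  but not the MT drag ("depends on MT length"); MT drags use rigid-rod
  slender-body formulas with a nucleoplasm viscosity parameter
  (`microtubule.viscosity_pa_s`).
- **Kinetics cadences**: motor/crosslinker/AF kMC and bound-head motion
  run every `kinetics_stride` BD steps (default 5, i.e. every 44.5 µs —
  well below every kinetic and mechanical relaxation time; the softest
  relevant spring relaxes in ≈140 µs).  Geometry-dependent association
  rates (neighbor integrals) are refreshed every `binding_refresh_steps`
  steps (default 100 ≈ 0.9 ms, short compared to diffusive rearrangement
  of the relevant geometry); when an event fires, the target is
  re-enumerated at the current geometry.  AF events use the configured
  N_kmc = 10 substeps, compounded exactly into one draw per step.
- **Quadrature**: second-head and AF binding integrals discretize the
  candidate filament into 4 nm segments over the window where the
  Boltzmann weight exceeds ~e⁻⁸; outside it the integrand is negligible.
- **Reproducibility**: one inline xorshift128+ stream seeded from the
  run seed; all draws are ordered by entity index, so identical
  (parameters, seed) give bit-identical trajectories on one platform.
  Observable sampling draws nothing, so the sampling stride cannot alter
  the dynamics.
- **Degenerate inputs**: zero-length spherocylinders are treated as
  spheres; exactly perpendicular axis pairs break alignment ties toward
  antipolar; exponent arguments in Bell factors are clamped at +50 to
  avoid overflow under force clamps.

## Initial condition

Side-by-side SPBs separated by the 75 nm bridge on the envelope,
linked for the first 5 s (the tabulated linkage time) by a bridge spring
that holds the pair at the bridge separation until the motor/crosslinker
network takes over; 14 MTs
per SPB at the 75 nm minimum length, growing, with minus ends at the
tether rest distance from their anchors and axes drawn uniformly over
the inward-facing hemisphere (the published schematic shows short MTs
splayed in all directions around the SPBs; a broad splay also supplies
the initial antiparallel contacts from which kinesin-5 sliding
bootstraps bipolarity).  Three chromosomes are rejection-sampled
300–750 nm inside the SPBs with the pole-facing sister oriented toward
them (monotelic-compatible) and no steric overlaps.  All motors,
crosslinkers, and attachment factors start unbound.

## Scaled-down study conditions

The published study conditions are 12–24 replicates of ~25 simulated
minutes per parameter point — cluster-scale work.  The test suite and
the acceptance script run the same model at desk scale: a few replicates
of a few simulated minutes, which suffices for the qualitative contrasts
(reference assembles a bipolar spindle; kinesin-5 deletion and loss of
crosslink stabilization do not) and for the analytic and equilibrium
checks, but not for converged biorientation fractions or length
fluctuation statistics, which require the full horizon.  The time step
is never changed in scaled-down runs.

## What the synthetic conditions do not capture

The generator emulates the model's own initial condition, not real
imaging data: there is no photon noise, no tracking error, and no
cell-to-cell parameter variability.  Passing tests demonstrate internal
consistency (detailed balance, force-energy consistency, analytic
dynamic-instability limits, classification correctness) and the model's
qualitative genetics, not agreement with any particular cell.  Known
limitations carried over from the model class: kinetochore-MT attachment
keeps turning over at steady state (real metaphase biorientation is
essentially permanent once established); kinesin-14 minus-end anchoring
at poles is neglected; MT number per SPB is fixed at 14; chromatin is a
rigid spherocylinder rather than a polymer.

**De novo bipolarity at desk scale.**  The most important known
limitation of this implementation: with the published parameter values
and the binding conventions pinned by the equilibrium invariants above,
the emergent escape from the side-by-side monopolar state does not occur
within the desk-scale horizons we can run.  Detailed instrumentation
shows every component working as designed — antiparallel kinesin-5
engagements form early (about 44% of cross-pole motors a few seconds in)
and a hand-constructed bipolar geometry is slid apart at the expected
speed and in the expected direction — but the crosslinker network binds
up the short-MT cluster within seconds, microtubule elongation plus
envelope torque funnel all orientations into an inward-pointing
monopolar aster, and the remaining cross-pole kinesin-5 engagements are
polarity-aligned, producing net inward force that makes the monopolar
state mechanically stable.  Establishing the bipolar state evidently
depends on model details and parameter calibration beyond the published
tables (the original model's parameters were fitted with a dedicated
optimization pipeline against live-cell data).  Consequently the
perturbation contrasts hold only in one direction at desk scale
(kinesin-5 deletion and stabilization loss stay monopolar, as they
should), and the biorientation-dependent observables (biorientation
fraction, interkinetochore stretch under tension, anaphase triggering)
are exercised by unit-level and constructed-geometry tests rather than
by emergent full-system runs.
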