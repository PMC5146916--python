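# Methods

`poretrans` simulates the forced translocation of a coarse-grained
single-stranded-DNA model through a nano-pore carved in a graphene-like
membrane, and analyses the resulting first-passage (translocation-time)
statistics.  Everything is expressed in reduced Lennard-Jones units
(`a = sigma_P = m = epsilon = k_B = 1`); `poretrans.units` maps these onto
0.3 nm, 1.6e-25 kg and 2.74e-21 J, giving 9.1 pN per force unit, 2.3 ps per
time unit and 300 K at the polymer temperature T_p = 3/2.

## Model

**Polymer.**  A flexible bead-spring chain mimicking ssDNA at the coarsest
useful level: phosphate-like (P) and sugar-like (S) beads alternate along
the backbone and one base-like (B) bead is grafted to every S; one extra P
heads the chain and receives the pulling force, so `n` repeats give
N = 3n + 1 beads.  Bead diameters are sigma_P = sigma_S = a, sigma_B = 1.5a,
all masses 1.  Every bead pair repels through the WCA potential (12-6 LJ
truncated at 2^(1/6) sigma_ij and shifted so energy and force vanish there),
with sigma_ij = (sigma_i + sigma_j)/2.  Adjacent S-P and S-B pairs
additionally feel the attractive finitely extensible term
-K R_ij^2/2 ln(1 - (r/R_ij)^2) with R_ij = 1.5 sigma_ij; the sum is the FENE
bond.  The FENE prefactor is K = 30 eps/sigma_ij^2, the standard
Kremer-Grest value, configurable.  There is no bending, torsion,
electrostatics, hydrogen bonding or explicit solvent; hydrodynamics is
absent by construction of the Langevin dynamics.

**Membrane.**  C beads on a honeycomb lattice in the z = 0 plane, periodic
in x-y, open in z.  Membrane-membrane pairs interact with sigma = a/3 (only
when the membrane is mobile), membrane-polymer pairs with sigma = a, which
makes the sheet impenetrable between beads.  In the *immobile* mode the
beads are frozen force sources; in the *kinetic* mode each bead is tethered
to its lattice site by U = k/2 |r - r_o|^2 (k from 75 to 1e4; k = infinity
is the immobile limit) and coupled to its own thermostat at T_m in [0, T_p].

**Lattice convention (calibrated).**  The stated lattice constant b = a/2
does not by itself fix the sheet.  Requiring that carving a pore of radius
R_s = 1.25a removes exactly 24 sites and R_l = 1.75a removes 54 — the
coronene/circumcoronene motifs — forces the pore center onto a hexagon
center and the nearest-neighbour spacing d into [0.347a, 0.401a].  We fix
d = 3a/8 = 0.75 b: inside that window, and a 49 x 28-cell periodic patch
then holds exactly 5488 sites in a 31.8a x 31.5a box, large enough that the
N = 49 chain at its rest contour (~31a) cannot reach its own periodic
image.  The convention is recorded in every lattice's metadata, and the
literal `b = bond` reading plus site/bond-midpoint origins remain available
as options.

**A consequence worth knowing.**  With this calibrated geometry the
innermost ring of the small pore sits at 1.35a, leaving an aperture of only
~0.45a (halfwidth, for bead centers).  An S bead's three bonded arms (two
backbone P at ~0.96a and its B at ~1.2a, with sigma_PB = 1.25a) cannot
straddle the membrane plane inside that cylinder without O(10 eps)
overlaps, so immobile-membrane translocation through R_s is an activated
process that effectively stalls below f ~ 30 and proceeds quickly above
f ~ 40.  The large pore R_l (inner ring 1.875a) shows no such frustration
at any force.  All qualitative orderings — R_s slower than R_l, deformable
(kinetic, T_m = 0) membranes faster than immobile with the speed-up growing
as k decreases, and membrane heating at k = 300 slowing translocation back
down — hold in this geometry and are asserted by the test suite at f = 40
with an n = 6 chain, where every condition translocates.  One derived sign
differs from the wide-pore picture: the time-averaged effective pore radius
during a soft-tether (k = 75) passage falls *below* its static value,
because the cis-side coil presses rim beads inward during stalls; the pore
still opens transiently while beads squeeze through.

## Dynamics

Underdamped Langevin dynamics, m r'' = -grad U - xi r' + eta(t) with
<eta_i eta_j> = 2 xi k_B T delta_ij delta(t - t'), integrated with the BAOAB
splitting; the O sub-step uses the exact Ornstein-Uhlenbeck damping
exp(-xi dt/m), so the scheme is stable at any xi dt and reduces to velocity
Verlet at xi = 0 (verified by an energy-drift test).  Defaults: dt = 5e-3,
xi = 1, T_p = 3/2; the membrane group is thermostatted separately at T_m,
where T_m = 0 retains the friction but no noise.  Frozen beads (immobile
membrane, the pinned head during thermalization) are excluded from
integration but remain force sources.

Neighbour candidates come from a kd-tree over the membrane anchor sites:
polymer-membrane pairs within cutoff + skin (0.75a) + tether budget, and
membrane-membrane pairs within cutoff + twice the budget.  The compiled
inner loop monitors polymer displacements against the half-skin and
membrane displacements against the budget (0.35a, escalated 1.5x and
rebuilt if ever exceeded), so the candidate list is always a superset of
the interacting pairs; a 200-configuration oracle test checks neighbour-list
forces against the O(N^2) evaluation at 1e-10.

## Translocation protocol

Each trajectory: grow the chain self-avoidingly into z < 0 with all bonds
at their FENE rest length, pin the head P bead at the pore center (0,0,0),
thermalize (default 2e5 steps; scaled-down profiles use shorter runs and a
warning fires below twice the Rouse time xi N_b^2/(3 pi^2 T_p)), then at
t = 0 release the head with a thermal velocity and switch on the constant
force F = 1.5 f along +z.  The run ends when all polymer beads have z > 0
(checked every 10 steps; the step count is the translocation time), when
the chain abandons the pore (head beyond 4a laterally while cis-side,
sustained for 1e4 steps — recorded as a failed slide and excluded from
statistics, with the thresholds declared here, not inferred), or when the
step budget runs out (timeout).  Per-trajectory observables: per-bead
residence time in the pore slab |z| < sigma_B, first-crossing step of each
bead (whose sorted differences expose the stalls caused by B-bead passage),
and in the kinetic mode the effective pore radius R_eff(t) = min over rim
beads of (planar distance - a/2), the rim being the sites initially within
one lattice spacing outside the pore.

Ensembles derive per-trajectory seeds from (master seed, trajectory index)
via `SeedSequence(entropy, spawn_key)`, making results independent of
execution order or worker count; the shipped runner is serial.

## Analysis

Mean translocation times and standard errors use successful records only;
an all-failure ensemble raises rather than returning zero.  tau* ratios
propagate errors in quadrature.  Translocation-time histograms are fitted
by the inverse-Gaussian (Wald) first-passage family via its closed-form MLE
(mu = sample mean, 1/lambda = mean(1/t - 1/mu)), with log-likelihood and a
KS statistic reported and scipy's generic fit as an independent
cross-check in the tests.  Power laws (tau ~ f^-gamma, R_g ~ n^nu, D ~ N^x)
are weighted least squares in log-log space; the default regime windows are
f >= 10 (high) and f <= 4 (low), the guide-curve two-power-law and
exponential low-f alternatives are available but never used for headline
exponents.  The free-chain diffusion constant comes from the long-time
slope of the time-origin-averaged center-of-mass MSD, fitted with an
intercept because the underdamped transient shifts the MSD by a constant
without changing its slope.

## Problem sizes of the shipped studies

Chosen so each study runs in minutes on one core with statistical errors
well inside the quoted bands:

* force scaling: 30 trajectories at each f in {10, 20, 40}, N = 49, large
  pore, immobile membrane, 3e4-step thermalization; typical result
  gamma = 0.97 +/- 0.02.
* diffusion scaling: n in {4, 8, 16}, 40 replicates of 3e4 steps each; the
  chain's center of mass is an exact OU particle (internal forces cancel),
  so no equilibration is needed; typical exponent -1.03 +/- 0.06.
* Flory scaling: n in {4, 8, 16, 32}, 80 samples of sqrt(<Rg^2>) spaced
  three Rouse times after a ten-Rouse-time burn-in (the grown start is
  artificially elongated, so generous equilibration matters); typical
  nu = 0.63 +/- 0.02, the converged apparent exponent of this
  side-chain-decorated chain at these lengths, on the low side of the
  0.69 +/- 0.08 finite-size band.
* orderings: n = 6 chain, f = 40, N_t = 8-12 matched-seed trajectories per
  membrane condition (see the frustration note above for why this force).

## What the synthetic studies do and do not show

All inputs are generated programmatically; there is no external data.  The
scaled-down ensembles demonstrate the model's physics (drift-dominated
1/f scaling, Rouse-like D ~ 1/N, self-avoiding R_g growth, the
deformability/temperature orderings) with small-sample statistics; they do
not reproduce published low-force quantitative ratios, which require ~1e3
trajectories of ~1e8 steps (full-scale configs under `configs/`), and in
this calibrated geometry the immobile small-pore reference does not
complete at low force at all.  Real ssDNA features deliberately absent from
the model — base identity, stacking, hydrogen bonding, backbone stiffness,
electrostatics, hydrodynamic coupling — limit any direct experimental
mapping.

## Numerical choices and degenerate inputs

Carving uses a strict inequality (sites exactly at R survive); carving is
idempotent and monotone in R.  n = 0 chains (a single pulled bead) are
allowed for oracle tests.  A bond reaching its FENE maximum raises a
dedicated error naming the bond (the cure is a smaller dt or weaker force),
as do non-finite coordinates.  Growth failures after bounded retries raise
instead of silently truncating the chain.  Requested box extents must be
commensurate with the lattice period; the error lists the nearest valid
sizes.  All-equal translocation times make the first-passage fit degenerate
and are rejected.
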