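# Methods

`isletvmo` simulates a vascularized islet micro-organ (islet-VMO): a
microfluidic chamber in which human pancreatic islets sit in a fibrin gel
threaded by living, perfusable capillary-scale vessels, flanked by an
arteriole-side channel C1 and a venule-side channel C2 with medium
reservoirs V_A–V_D at the channel ends.  The package reproduces, in
silico, the device's glucose-stimulated insulin secretion (GSIS) assay
and its associated quantification procedures.  This note records the
model, its assumptions, the parameters that matter, and the design
choices made where the design was genuinely open.

## Geometry

All geometry is two-dimensional with a uniform out-of-plane depth
h = 200 µm (a single photoresist layer).  The continuous description —
chamber rectangle, channel rectangles, boundary ports, vessel skeleton
(polyline midlines with per-edge diameters), islet discs — is rasterized
onto a uniform cell grid with material labels WALL < GEL < ISLET < LUMEN
(ascending paint precedence: a vessel crossing an islet's rim stays
open, since lumenized vessels do not penetrate islet tissue and flow
integrity comes first).  Cell ownership is by cell center; the raster
spacing must not exceed half the smallest vessel diameter, or thin lumen
strips would disconnect.

The chamber's lateral dimensions are not a measured quantity here; the
default is 6 mm × 2 mm with 200 µm channels on the long sides, which
comfortably houses a ~20-islet loading of sub-200 µm islets.  Everything
downstream parameterizes on the configured value.

Morphometrics follow the conventions used for traced vessel networks:
total length is the sum of midline arclengths; branch points are nodes
of degree ≥ 3 after merging nodes closer than a 10 µm tolerance (traced
junctions are imprecise; the tolerance must exceed the raster spacing);
diameters are sampled every 50 µm of arclength per edge, half-open (the
position at 0 included, an endpoint falling exactly on a multiple of the
interval excluded), one sample minimum per edge.

## Flow

Medium is driven hydrostatically: each open reservoir imposes
p = ρ g·head on its port faces.  Because the device is shallow, the
free-and-porous-media problem is reduced to a heterogeneous
depth-averaged Darcy/Hele-Shaw equation, ∇·(m∇p) = 0, with mobility
m = h²/(12µ) in lumen (exact for shallow channels), κ_gel/µ in gel and
κ_islet/µ in islet tissue.  Islets are porous rather than solid
obstacles (nothing suggests they block interstitial flow, and solid
inclusions would create singular pockets); by default κ_islet = κ_gel =
1e-15 m², a representative fibrin permeability, and all constants are
configuration values.  At 200 µm depth and ≤100 µm vessel widths the
neglected inertial and lateral shear corrections are secondary; the
discretization is validated against the Hele-Shaw and 1-D Darcy closed
forms (1% and 0.5%).

Discretization: cell-centered finite volume, harmonic-mean face
mobilities (standard for discontinuous coefficients), direct sparse
solve.  Face fluxes are discretely divergence-free; the conservation
report checks the worst cell divergence and the net port imbalance
(≤1e-8 relative in practice).

In the GSIS configuration V_B and V_C are blocked so all perfusate
crosses the chamber through the vessel network; V_A carries a 10 mm
head (the experimental heads are not recorded; this is a configuration
default) and V_D collects at zero head.

## Transport and islet kinetics

Oxygen, glucose and insulin obey advection–diffusion–reaction on the
raster over the frozen flow field, with per-material diffusivities
ordered D_INS < D_GLC < D_O2 (molecular size), inlet Dirichlet
concentrations at inflow port faces, advective outflow at the outlet,
no-flux walls for glucose and insulin, and an oxygen wall condition for
the gas-permeable device body: Dirichlet at the atmospheric-equilibrium
concentration c_atm = 0.2 mM by default (the simplest reading of
medium equilibrated with atmospheric oxygen), or a Robin film
coefficient optionally.  Internally everything is SI; conveniently
mol·m⁻³ ≡ mM.

Islet cells carry volumetric kinetics of the classical
local-concentration family:

* oxygen uptake R_O2,max·c/(c+K_M,O2), with R_O2,max = 0.034 mol m⁻³ s⁻¹
  and K_M,O2 = 1 µM — islet cores then sit at a few to ~90 µM, i.e.
  visibly hypoxic but above the c_crit = 0.1 µM cutoff below which all
  islet activity stops;
* glucose uptake R_GLC,max·c/(c+K_M,GLC) (small: ≲0.3 mM drawdown);
* insulin secretion R_INS,max·[b + (1−b)·Hill(c_GLC)] with
  Hill(c) = cⁿ/(cⁿ+K_INSⁿ), plus a first-phase term
  k₁·max(∂c_GLC/∂t, 0) converting a rapid local glucose rise into a
  transient burst.  KCl depolarization is a schedule flag forcing
  release at the maximal rate (releasable-insulin assay); granule-store
  depletion and a distinct second phase are deliberately not modeled —
  hydrogel-embedded islets show no distinct second phase, and the
  observable here is 10-minute-binned effluent.

An optional switch modulates oxygen uptake by local glucose (off by
default; some variants of this kinetic family include it).

Secretion constants were calibrated once, against the two observables
this family can reproduce: K_INS = 10 mM, n = 4 and basal fraction
b = 0.2 set the steady stimulated/basal secretion ratio at ≈3.4 for the
5.5 → 16.7 mM step (and, because insulin transport is linear, the
steady effluent fold change equals the secretion-rate ratio); the
first-phase gain k₁ = 1.15e-3 was then set from the simulated ensemble's
bin-wise impulse response so the first post-stimulation 10-minute bin is
the per-device peak at a mean peak fold consistent with perfused-device
measurements.  R_INS,max only sets the absolute insulin scale, which
cancels in fold change.

Numerics: first-order upwind advection and harmonic-mean-face diffusion,
advanced with backward Euler on one factorized sparse operator per
species.  Consumption is split off and integrated pointwise-implicitly
(the Michaelis–Menten update has a closed-form positive root), so the
scheme is unconditionally stable and positivity-preserving and the time
step is purely an accuracy knob — necessary because lumen velocities
(~cm/s at a 10 mm head) would make any explicit advection step
prohibitively small.  A run is initialized at the coupled steady state
of the first schedule segment (standing in for the basal pre-perfusion
hour): oxygen and glucose by damped Picard iteration on the sink
strength against the cached steady operator (damping settles cells where
demand exceeds supply), insulin by one linear solve.  When the
glucose→oxygen modulation is off, the oxygen problem is autonomous with
constant inputs, so a run started at the steady oxygen field keeps it
frozen — the transient solve is skipped as exact, not approximated.

Because insulin feeds back on nothing, the insulin sub-problem is linear
in its sources: many insulin fields (one per islet subset) advance
against the same operator in a single pass as a multi-column solve.
Per-islet attribution silences secretion (never consumption) of all but
one islet, so oxygen and glucose fields are identical across the runs
and the single-islet series superpose exactly to the all-islet run —
verified to <1e-6 relative, and a matrix column is verified to equal an
honest separate run.

## GSIS protocol and effluent analysis

The standard protocol: one hour of basal 5.5 mM glucose, one hour of
16.7 mM high glucose (t = 0 at the switch), two hours of recovery, one
hour of 30 mM KCl.  Effluent at V_D is integrated into 10-minute bins
from −30 min; the bin's glucose is amount over collected volume (what a
glucometer reads on a pooled fraction) and insulin is amount per bin
(pmol).  Fold change divides each bin by the mean of the −20–0 min
starvation bins; a zero baseline (e.g. secretion-dead kinetics) is
reported as an error flag with the glucose trace intact.  Reservoir dead
volume and tubing dispersion are not modeled and would shift observed
timings slightly.

The vessel-addition experiment appends one edge to the skeleton (it must
touch the existing network or a channel interface), reruns the protocol,
and reports cumulative outlet insulin plus the peri-islet extravascular
pool — insulin in gel cells within 100 µm of the target islet's rim (the
same halo radius as the immune adjacency rule, for consistency).

## Synthetic data

The generators define the study conditions; they are deterministic in
(seed, parameters) with sub-streams split per purpose.

* **Vessel networks**: a jittered lattice of candidate nodes plus anchor
  nodes on the channel interfaces, Delaunay candidate edges, a backbone
  of shortest C1→C2 paths for guaranteed perfusability, then shuffled
  edges attached to the growing network until the total-length target
  (default 25 mm per chamber) is met, topping up anastomoses if the
  branch count undershoots.  Edge diameters are lognormal
  (ln-mean 3.55, ln-SD 0.22) clipped to 25–150 µm; the 25 µm floor is
  the capillary caliber below which these networks are not traced, and
  it bounds the raster spacing from above.  The branch-density default
  (1.33 mm⁻²) is the value emergent from the length target on the
  default chamber, so the two targets are mutually consistent.  Real
  traced networks differ in ways the generator does not emulate —
  curved midlines, diameter taper, pruning history — so passing tests
  constrain the pipeline, not vascular biology.
* **Islet loadings**: count ~ Poisson(density × gel volume) with density
  22.5 µl⁻¹ and an effective loaded volume of 0.889 µl chosen so the
  expected count is the observed ~20 per chamber (the physical loaded
  volume is not recorded); positions uniform with rejection of
  islet–islet and islet–lumen overlap (large islets placed first);
  diameters lognormal (ln-mean 4.4247, ln-SD 0.35) truncated at the
  200 µm hand-selection cutoff, giving a truncated mean of 87.9 µm.
* **Point scenes**: immune-cell positions are placed strictly inside
  their truth class with a 2 µm clearance from every class boundary, so
  classification round-trips exactly; live/dead scenes place dead marks
  on an exact subset of nuclei at the requested fraction.

## Quantification

A PBMC in a lumen raster cell is adherent; otherwise inside an islet
disc, invasive; otherwise within 100 µm of the nearest islet boundary
(boundary-inclusive, Euclidean point-to-disc distance), islet-adjacent;
else background.  The labels partition the points.  Control ROIs — one
translated copy per islet ROI — are placed by seeded rejection sampling
(reproducible, exported for audit) avoiding islet discs and previously
placed ROIs; a switch additionally avoids the adjacency halos.  Dead
nuclei are matched to Hoechst nuclei greedily by distance within 5 µm
(nuclear scale), one mark per nucleus; unmatched dead points are
reported separately, not counted.

## Problem sizes and tolerances

Single-run analyses default to a 10 µm raster and 1 s steps.  Ensemble
surveys (ten devices, protocol truncated to −30…+70 min) use a 12.5 µm
raster — the finest spacing admitted by the 25 µm minimum vessel
caliber at reasonable cost — and 5 s steps; the binned observables are
insensitive to this (the first-phase term integrates to gain × Δc
regardless of step size).  Grid convergence of the outlet insulin
series was checked on a reduced device between 12.5 and 6.25 µm.  Flow
solves use a direct sparse factorization (residuals ~1e-11); steady
Picard iterations stop at 1e-9 relative sink change; the glucose mass
audit (inlet − outlet − consumption − accumulation) closes to round-off,
far inside its 0.5% contract.

## Known limitations

* 2-D only; no vessel compliance, no transient flow, no Brinkman shear
  layer at the lumen–gel interface.
* No granule-pool (biphasic) secretion dynamics, no somatostatin or
  glucagon cross-talk, no cell-death feedback on kinetics.
* Kinetic constants are literature-scale configuration defaults
  calibrated end-to-end to fold-change observables, not fitted to any
  per-device trace; absolute insulin amounts are not meaningful.
* The synthetic vessel generator controls summary morphometrics, not
  the spatial statistics of real angiogenesis.
* Reservoir dead volume and tubing dispersion are ignored, a known
  source of timing offset against bench measurements.
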