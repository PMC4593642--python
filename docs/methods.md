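# Methods

`filosim` is an individual-based, force-based model of filopodia-driven cell
invasion into a three-dimensional extracellular-matrix (ECM) fiber network.
Four coupled modules — filopodium penetration dynamics, intracellular
mechanics of a triple-membrane cell, fiber-network structural mechanics, and
reaction–diffusion mass transfer of the proteolysis/chemotaxis biochemistry —
advance together in overdamped dynamics.  This note records the model, its
assumptions, the numerical choices, and what the scaled-down studies do and
do not demonstrate.

## Unit system

All mechanics use μm / s / pN (energies in pN·μm = 1e-18 J); concentrations
are molar.  In these units 1 Pa = 1 pN/μm², 1 N/m = 1e6 pN/μm and
1 N·s/m = 1e6 pN·s/μm, so the tabulated SI constants convert by fixed powers
of ten.

## ECM fiber network

**Generation.**  Crosslink seed points sit on a cubic lattice at the target
pore spacing with ±12% uniform jitter; candidate fibers are Delaunay edges
no longer than 1.45× the pore size.  Each crosslink-to-crosslink line is
split into `n_div` fiber segments plus two 30 nm crosslink segments
(`n_div` = 1/2/3 for the 0.5/1.0/1.5 μm presets, keeping the density of
collagen molecules per fiber node constant at 300).  Segment sets continue
through a crosslink as one extended fiber when the bend away from straight
continuation is below 60° (equivalently, the angle between the two
outward-pointing directions exceeds 120°); this convention produces long
multi-segment fibers out of near-collinear edges.  Each incident fiber end
is crosslinked independently with probability `p_f` = 0.7.  The mean
nearest-crosslink spacing lands within ~10% of the target pore size.

**Elasticity.**  A fiber of radius r and Young's modulus E_f (1 MPa
default) has stretching modulus κ_s = E_f·π r² and bending modulus
κ_b = E_f·π r⁴/4.  Chain energy is κ_s/2 Σ (L−L0)²/L0 over segments plus
κ_b/2 Σ (θ−θ0)²/L0 over coaxial node triples; forces are the exact negative
gradient.  Near collinearity the angle-gradient factor (θ−θ0)/sin θ is
series-guarded; straight rest states (θ0 = 0) therefore have a finite,
correct limit.  Computing κ_b from first principles gives
(3.0–12.8)×10⁻² pN·μm² for the 28–41 nm fibers; the parameter is exposed as
an override because reported bending stiffnesses for collagen vary by an
order of magnitude.

**Degradation.**  Each node carries an ECM concentration (initially 10 μM);
its integrity I = C_ECM/C_ECM0 sets the number of detached fibers at a
crosslink node, N_uf = round_half_up((1−I)·N_0f), with newly detached
couplings drawn uniformly among the survivors.  Detachment removes only the
30 nm coupling: nodes, chains and fiber segments persist (a degraded
network becomes a suspension of free fibers that still interact sterically).
Crosslinks never re-form.

**In-silico rheology.**  The stretch test moves both boundary faces
symmetrically and relaxes the interior quasi-statically between strain
increments using a FIRE minimizer (identical fixed points to the overdamped
integrator, much faster); stress is the summed axial grip reaction over the
undeformed cross-section, and the bulk modulus is the least-squares slope
over strain 0.2–0.7.  The lab protocol's 0.25–1 nm/s stretch speeds are far
below the network relaxation scale, so the quasi-static limit is the
appropriate model; the nominal speed is kept as metadata.

## Filopodium

A filopodium is a chain of nodes spanned by 8 contractile acto-myosin (AM)
compartments (stiffness κ_AM = E_AM·A_AM/L¹ with E_AM = 230 kPa,
A_AM = 7.07×10⁻² μm²); the root is a cell-membrane node.  Phases follow a
seven-state machine (inactive, active, outgrowing, tugging, contractile,
retractile, decay) with length gates L_min = 2 μm and L_max = 4.5 μm.

* **Outgrowing**: a 2 nN protrusion force acts on the tip along the local
  VEGF gradient (falling back to the growth axis in a uniform field).
  Compartment rest lengths extend at a polymerization rate v_poly
  (default 50 nm/s, chosen to land tip extension in the μm/min range seen
  for endothelial filopodia) but never overtake the spans by more than
  10 nm, so the shaft stays taut and the tip advances at ~v_poly.
* **Tugging/contractile**: rest lengths shorten at 2·v_m per compartment
  with the whole-muscle force–velocity law
  v_m = v_m0(F_stall−F)/(F_stall+c_m F) (v_m0 = 10 nm/s, F_stall = 1 nN,
  c_m = 0.1) driven by the current focal-complex tension.
* **Retractile**: the focal complex is released and motors run unloaded,
  shortening the filopodium toward L_min and decay; a decayed filopodium
  frees its slot for re-nucleation.

**Focal complex (FC).**  One bond cluster per filopodium, restricted to the
tip.  An FC can form when the tip is within 100 nm of a fiber segment; the
anchor is the nearest segment point (deterministic tie-break toward lowest
fiber/segment id) and is re-projected to the closest point every event step,
so tip crawling along fibers is emergent.  Receptors (300 at the tip) bind
free ligands of the nearest fiber node with p = 1−exp(−k_f·(C_L−C_b)·Δt)
and rupture by the Bell slip law k_off = k_off0·exp(κ_LR(L_b−λ)x_b/k_BT)
(κ_LR = 1 pN/nm, λ = 30 nm, x_b = 0.02 nm, T = 310 K, so the characteristic
per-bond rupture force k_BT/x_b ≈ 214 pN).  Compression never accelerates
rupture.  The cluster force n_b·κ_LR·(L_b−λ) applies to the tip with the
exact opposite load interpolated to the two anchor-segment ends.  A cluster
stretched beyond 0.5 μm detaches geometrically (its Bell lifetime at that
extension is well under a second anyway).

**Contractile gate.**  The tension threshold for tugging→contractile is the
literature per-length value 3–4 nN/μm times the 0.3 μm filopodium diameter.
The stall force caps motor-generated tension at 1 nN, so the midpoint
(1.05 nN) would be unreachable; the gate uses the lower end,
3.0 nN/μm × 0.3 μm = 0.9 nN, exposed as a config scalar.

**Timers.**  The phase budgets (outgrowing → retractile and tugging →
retractile timeouts, both 60 s; a 300 s contractile safeguard) and the 45°
polarity-angle gate with at most 4 concurrent filopodia are configuration
choices: the state machine names these timers without printed constants.

## Cell body

Three concentric 549-node shells (cell membrane, transduce layer, nuclear
membrane) share one triangulation.  Membrane and nucleus carry edge springs
(κ_memb = 5×10⁻⁵ N/m) plus a volume-preservation penalty (the "elastic
energy force" is not expanded beyond this); each membrane node couples to
its transduce partner through a cortical Kelvin–Voigt element — spring
κ_cort = 8×10⁻³ N/m in the force balance, dashpot C_cort = 0.006 N·s/m in
the coupled per-node 2×2 mobility

    (C_c+C_cort) ẋ_c − C_cort ẋ_t = ΣF_c
    −C_cort ẋ_c + (C_t+C_cort) ẋ_t = ΣF_t.

Focal adhesions (FAs) reuse the FC bond machinery with a 100-bond cap and a
5× slower unstressed off-rate (their turnover exceeds 5 minutes where FCs
live under one); they anchor membrane nodes to the nearest fiber point
within 100 nm.  Mature FAs (≥30 bonds) nucleate a stress fiber — a single
AM compartment from the transduce node to the nearest nucleus node,
contracting under its own force–velocity law.  A constant 300 pN
lamellipodium force pushes leading-edge nodes (outward normal within 60° of
the polarization axis); polarization follows an exponential moving average
of the centroid displacement direction.  The detailed FA-maturation and
stress-fiber remodelling models this descends from are deliberately
minimal here: the force balance and every action–reaction coupling are
kept, the remodelling biochemistry is not.

## Reaction–diffusion and degradation coupling

Seven species on a regular Cartesian grid (1 μm default): diffusing VEGF,
MMP-2 (both 68.8 μm²/s), TIMP-2 (1.29 μm²/s) and free ligand (10⁻³ μm²/s);
non-diffusing membrane-associated MT1-MMP and the ternary
MT1-MMP:TIMP-2:proMMP-2 complex; plus the ECM concentration field.
Reactions: first-order decay of VEGF/MMP-2/ligand; TIMP-2+MMP-2 association
(a sink for both); TIMP-2+MT1-MMP association forming the complex;
activation of MMP-2 by a second MT1-MMP acting on the complex (the complex
is consumed — the alternative sign, which makes the complex autocatalytic
and divergent, is switchable for completeness); ECM proteolysis
dC_ECM/dt = −k_deg·C_MMP2·C_ECM with k_deg = 1.04×10⁶ M⁻¹s⁻¹, liberating
ligand exactly as fast as ECM is consumed; and TIMP-2/MT1-MMP secretion at
the grid cells containing filopodial roots at rates α·C_Ligand
(α = 10⁻³ and 10⁻¹ M/s; a constant-rate variant is switchable).

Numerics: diffusion by one backward-Euler finite-volume solve per species
and step (direct sparse factorization, cached; the zero-flux operator
conserves mass to solver precision); reactions by a positivity-preserving
semi-implicit (Patankar) update, sub-stepped against the fastest
self-loss rate.  VEGF is pinned on the far domain face (default 1.3 nM,
≈50 ng/ml) to maintain the chemotactic gradient; all other faces are
zero-flux.  Node-attached ECM concentrations decay by the exact exponential
under the locally interpolated MMP-2 and feed crosslink detachment.

Initial conditions are assumptions (not printed anywhere authoritative):
ligand and ECM at 10 μM (2.5 mg/ml collagen at ~300 kDa), a linear VEGF
ramp toward the pinned face, all other species zero.  Because every wall
except the VEGF face is zero-flux, secreted MMP-2 accumulates in the small
simulation box over hundreds of seconds; late in a run degradation is
therefore strong everywhere near the cell, not just at filopodial roots.
A medium channel that washes protease away would localize degradation more
sharply; that geometry is not modelled.

## Engine

All mechanical nodes live in one flat state advanced by an adaptive
embedded Euler/Heun pair between *event steps* (default 0.05 s): bond
formation/rupture, anchor re-projection, AM rest-length updates, the state
machine and nucleation fire once per event step; reaction–diffusion,
degradation, FA/SF maintenance and polarization update every 0.5 s; the
active domain (nodes within 15 μm of the cell and tips; everything outside
is a frozen boundary) and spatial hashes refresh on their own timers.

The integrator's local error is the RMS of the embedded-pair difference
over mobile nodes, kept below `ode_tolerance` with steps clamped to
[dt_min, dt_max]; a step at dt_min is accepted and counted rather than
stalling the run.  Mobility uses v = F/max(C, dt·k_node), where k_node sums
the stiffness of interactions touching the node: below the overdamped
stability limit this is the exact mobility and the pair is second order
(verified against an LSODA oracle); beyond it the node relaxes dead-beat
toward its local equilibrium — a linearly-implicit treatment of the
dominant diagonal that leaves equilibria and forces untouched.  This is the
package's realization of an adaptive stiff scheme: a full Rosenbrock
Jacobian for 10⁴–10⁵ degrees of freedom would dominate the cost without
changing the minute-scale observables.

Contacts treat membrane and filopodial nodes against fiber cylinders with a
linear repulsion inside the contact radius, with exact reactions on the
segment ends.  Membrane nodes add an effective 60 nm radius to the fiber
radius so the finite-resolution membrane cannot slide between 20 nm fibers
unhindered (kept below the 100 nm adhesion gate so FAs still form);
filopodial nodes use the bare fiber radius so the contact shell never
blocks the 100 nm focal-complex gate.  Candidate pairs refresh every 0.5 s
through a uniform spatial hash; a fast-moving tip can therefore penetrate a
fiber for up to that interval before being repelled — an accepted
resolution artifact at these step sizes.

## Scaled-down studies (`filosim.studies`)

The pre-registered conditions for the package's computational experiments:

* **Rheology**: 10 μm pore-1.0 networks (one geometry per sweep), fiber
  diameters 28/34/41 nm at E_f = 1 MPa and E_f = 0.25/1 MPa at 34 nm,
  strain steps of 0.05 to a maximum of 0.75.  The claim tested is the
  monotone increase of the fitted modulus with diameter and E_f; absolute
  moduli (hundreds of Pa here) depend on network density and geometry and
  are not compared to experimental gels.
* **Invasion**: a 2 μm-radius cell in 15×5×5 μm networks, 10 simulated
  minutes, N = 5 seeds per pore preset; tip and root speeds are the
  path-length time averages of per-filopodium trajectories sampled at 1 s.
  The integrator rides dt ≤ 0.15 s at RMS tolerance 10⁻³ μm for these runs
  (the minute-scale speed statistics are insensitive to this; the default
  engine settings are tighter).  The claim tested is the non-decreasing
  ordering of replicate-mean speeds with pore size, not absolute speeds.
* **Proteolysis contrast**: the pore-0.5 invasion conditions for 5
  simulated minutes with degradation enabled vs disabled (an
  MT1-MMP-deficient cell), identical seeds, compared by mean cell-centroid
  advance along the invasion axis.

## What passing tests do and do not show

The synthetic networks reproduce the statistical targets of the original
gel models (pore spacing, segmentation, crosslink fraction, ligand
density), not any specific imaged gel; cells here stay rounded (549-node
shells), filopodia neither branch nor buckle, and bond kinetics are pure
slip bonds.  Agreement of the in-silico trends with the modelled claims
therefore supports the mechanism — stiffer/denser networks slow invasion
unless degraded — but says nothing quantitative about real HUVEC speeds or
measured gel moduli, which require the original full-scale geometries and
experimental data.

## Known limitations

* The closed RD box globally accumulates MMP-2 (see above), making late-run
  degradation spatially broad.
* The per-node deadbeat damping sacrifices transient accuracy of the
  stiffest, fastest-relaxing nodes at large steps; equilibria and the
  minute-scale statistics are unaffected, and the default engine settings
  keep nearly all nodes in the exact-mobility regime.
* Stochastic events are applied at the event-step cadence, so bond-level
  fluctuations faster than ~0.05–0.3 s are coarse-grained.
* A replicate that raises an exception is recorded as failed and excluded
  from summaries rather than aborting the study.
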