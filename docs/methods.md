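# Methods

## The model

`cleftpnp` simulates ionic electrodiffusion in an idealized glutamatergic
synapse: a cuboid domain containing a slab of presynaptic cell, its
membrane, the thin extracellular sheet between the two cells (whose central
600 x 600 nm part is the synaptic cleft proper), the postsynaptic membrane,
and a slab of postsynaptic cell.  Five ionic species are tracked — Na+, K+,
Ca2+, Cl- and glutamate (Glu-, carrying one negative charge).

Two transport descriptions are solved on the same mesh and compared:

* **PNP** (Poisson–Nernst–Planck).  Each concentration obeys

  ∂[k]/∂t = ∇·( D_k ∇[k] + D_k z_k e/(k_B T) [k] ∇φ ),

  coupled to the Poisson equation ∇·(ε_r ε_0 ∇φ) = −ρ with charge density
  ρ = F Σ_k z_k [k].  The potential has no dynamics of its own; it is
  determined instantaneously by the charge distribution.

* **D** (pure diffusion).  The drift term is dropped: ∂[k]/∂t = ∇·D_k∇[k],
  and no potential is part of the solution.  Where the receptor model needs
  a membrane potential, the D model uses the −70 mV holding value.

The questions the package answers are how much the two solutions differ
(fields, flux decomposition J_d = −D∇c vs J_e = −D z e c ∇φ/(k_B T), AMPA
current) under a single vesicle-release event, and how that discrepancy
responds to parameter changes.

## Unit system

All internal quantities live in nm / ms / mM / mV.  Two numerical
coincidences make the standard constants usable unconverted: 1 mM equals
1 mol/m^3, so F·z·c is a charge density in C/m^3; and with ε0 expressed in
fF/m (8854) the Poisson equation balances when gradients are per nm and φ
is in mV.  With k_B in mJ/K and e in C, e·φ/(k_B T) is dimensionless for φ
in mV (thermal voltage ≈ 26.71 mV at 310 K).  Single-channel conductances
stay in pS: g·(v−v0) is a per-channel current in fA, and the conversion of
the receptor flux formula into the internal molar flux density (mM·nm/ms)
is a single factor of 1e9 (`constants.AMPA_FLUX_SCALE`).

## Geometry and mesh

The y axis is normal to the cleft.  From y = 0: 1000 nm of presynaptic
cell, a 5 nm membrane, the 15 nm extracellular sheet, a 5 nm membrane, and
1000 nm of postsynaptic cell.  The cells and membranes span the full
1000 x 1000 nm lateral extent; only the central 600 x 600 nm of the sheet
is the cleft with restricted diffusion (bulk coefficients divided by
κ = 2.56).  A 40 nm cubic vesicle sits inside the presynaptic cell flush
against its membrane, connected to the cleft through a 4 x 4 nm opening in
the membrane; the opening also carries restricted diffusion, and it is open
from t = 0 (a single release event, never resealed).  The vesicle is a cube
rather than a sphere: a 40 nm cube at 150 mM holds ≈ 5.8e3 glutamate
molecules, consistent with the nominal "≈ 6000 molecules" load, whereas a
40 nm-diameter sphere would hold only ≈ 3e3; a cube is also the natural
shape for a rectilinear finite-difference code.  The 200 AMPA receptors are
spread uniformly over a 140 x 140 nm square of the postsynaptic membrane
centered above the release site.

The mesh is a tensor-product, cell-centered rectilinear grid.  Every
geometric boundary (membrane faces, vesicle, opening, AMPA square, cleft
edge) is snapped to a mesh edge, so region labelling by cell-center
containment is exact and region volumes are analytic.  Spacing is finest
across the cleft (at least three cells, i.e. ≤ h/3) and around the opening,
and coarsens geometrically away from the synapse with a configurable ratio
and size cap.  Two presets exist: `coarse` (ratio 1.9, cap 350 nm;
17 x 22 x 17 ≈ 6.4e3 cells) used for the desk-scale runs and tests, and
`fine` (ratio 1.25, cap 120 nm) for better-resolved studies.

Membrane cells carry no mobile ions (all concentrations 0, contributing
zero charge density) and have zero diffusivity, so they are frozen;
transport crosses the membrane only through the vesicle opening and the
AMPA interface fluxes.  The Poisson equation *is* solved through the
membrane with ε_r = 2 (vs 80 in the aqueous regions), which is what
produces the resting potential drop across the membranes.  The vesicle
opening is treated as an aqueous pore (ε_r = 80).

## Boundary and initial conditions

Dirichlet values are imposed on the domain faces adjacent to aqueous
compartments: 0 mV and the extracellular mixture at the lateral edges of
the extracellular sheet; −70 mV and the intracellular mixture on the outer
intracellular boundaries (both far faces in y and the lateral cell faces —
the reference geometry sketch suggests Dirichlet on the outer intracellular
boundary generally, and we apply it to every outer face adjacent to
intracellular cells).  Boundary faces adjacent to membrane cells, and all
internal walls, are no-flux.  Initial mixtures (mM): extracellular
Na 100 / K 4 / Ca 1.4 / Cl 106.8; intracellular Na 12 / K 125 / Ca 1e-4 /
Cl 137.0002; vesicle Na 145 / K 5 / Glu 150.  Each mixture is exactly
electroneutral (the Cl- values carry extra digits for that reason), so the
initial charge density vanishes identically.  The vesicle-opening cells are
initialized with the vesicle mixture.  The initial potential (0 mV
extracellular, −70 mV intracellular) is only a Newton starting guess: in
the PNP model φ is elliptic and relaxes to the self-consistent solution
within the first step, forming Debye layers along the membranes.

## Discretization and solvers

Cell-centered finite volumes.  Face diffusivities and permittivities are
distance-weighted harmonic means, which is exact for piecewise-constant
coefficients and makes membrane faces (D = 0) naturally impermeable.  The
drift term uses central differencing of φ with arithmetic-mean face
concentrations (an upwind donor-cell option exists for steep-gradient
robustness; the shipped scenarios use the central scheme).  Dirichlet
boundary values enter through half-cell face fluxes.

Time stepping is backward Euler with dt = 0.02 ms.  The D model is linear
and species-decoupled: one sparse LU per species is factorized once and
reused for the whole run.  The PNP system is advanced monolithically — all
five concentrations and the potential in one damped Newton iteration on the
coupled residual, with residual rows scaled to concentration units
(transport rows by dt/V, Poisson rows by 1/(F V)) and an infinity-norm
stopping rule of `newton_tol` (1e-8) times the concentration scale.  Newton
converges in 2–4 iterations per step on the shipped scenarios.

The linear Newton updates are solved directly (sparse LU) for systems up to
~12k unknowns.  Larger systems use GMRES with an approximate block-LU
preconditioner: the five species blocks and the potential block are scalar
seven-point operators that are cheap to factorize, and the potential block
is replaced by its approximate Schur complement — the Poisson operator
augmented with the Debye screening term obtained from diagonal transport
inverses.  The preconditioner is refreshed whenever a solve needs more than
140 iterations.  An inexact-Newton forcing of 1e-4 on the linear residual
leaves the converged states unchanged to ~1e-11 while saving roughly a
quarter of the Krylov work.

Negative concentrations are not clipped.  A step that produces a
concentration below −1e-10 mM is retried as two half steps (recursively, up
to 12 levels) and the nominal dt is restored afterwards; the shipped
scenarios never trigger this.

## Receptor coupling

AMPA gating follows a seven-state Markov chain (closed states C0–C5 bound
to 0–2 glutamate molecules plus desensitized states, and one conducting
state O).  The conducting-state probability is defined as the complement
o = 1 − (C0+...+C5), so the seven probabilities sum to one by construction
(any other complement convention would violate probability conservation
under the closed-state rate equations).  The
chain is integrated by operator splitting with classical RK4 at a 0.001 ms
substep, with the local glutamate concentration frozen over each transport
step; it is sampled at the cleft cell adjacent to each AMPA membrane face,
so each mesh element of the receptor area carries its own state.

The Na+/K+ fluxes through open receptors,
J_k = N_AMPA /(F w_a^2) · g_k · o · (v − v0_k), are *internal boundary
conditions of the implicit transport solve*, evaluated at the end-of-step
concentrations and potential: v = φ_i − φ_e sampled at the two cells
flanking the postsynaptic membrane (fixed at −70 mV for the D model), and
the Nernst potentials v0 from the same local concentrations on both sides.
This implicitness is essential — with ~200 receptors over a 15 nm cleft the
explicit flux overdraws the local K+ pool within a single 0.02 ms step and
oscillates; the implicit form self-limits because v0 diverges
logarithmically as a local concentration approaches zero.  The logarithm's
argument is clamped below 1e-6 mM so the restoring force saturates smoothly
instead of overflowing; a face whose start-of-step concentration is
actually nonpositive has its flux skipped for that step with a warning.
Fluxes are applied as paired sources (the cleft cell loses exactly what the
intracellular cell gains), so transmembrane transport conserves mass
globally, and the total current I_AMPA = ∫ F (J_Na + J_K) dA is integrated
over the receptor area with the mesh face areas (reported in nA; negative =
depolarizing inward).

## Comparison metrics

`compare_runs` pairs a PNP run with a D run sharing the mesh, initial data
and schedule.  The headline numbers are (i) the relative excess of the D
model's cleft-center glutamate over the PNP value at t = 0.5 ms,
([Glu]_D − [Glu]_PNP)/[Glu]_PNP, with the probe at the mesh cell containing
the geometric cleft center, and (ii) the relative difference of the signed
minima of the two I_AMPA traces, (|min I_PNP| − |min I_D|)/|min I_D|.
Probe positions are mapped to the nearest mesh cell and the mapping is
recorded.  Swapping the inputs inverts all ratios and negates all
differences.

## Verification oracles

* **Poisson–Boltzmann (1D).**  At equilibrium with zero-flux concentrations
  each species follows c_k(x) = A_k exp(−z_k e φ/(k_B T)) with A_k fixed by
  content conservation.  `poisson_boltzmann_oracle` solves this on its own
  uniform node grid (tridiagonal Newton for φ inside a fixed-point update
  of the A_k) and is compared against the stationary solution of the
  time-stepping PNP solver on the 10 nm interval problem (Na 100 / Cl 99 /
  Glu 1 mM, φ(0) = 0, φ(L) ∈ {−5, −10, −15} mV).  The deviation from
  uniformity grows monotonically with |φ(L)|.
* **Manufactured solution.**  φ* = sin(πx/L) with matching charge confirms
  second-order L2 convergence of the Poisson solve; a mesh-aligned
  permittivity jump (2 vs 80) is reproduced nodally exactly by the harmonic
  face averaging.
* **Heat kernel.**  A Gaussian profile under the D model spreads with
  variance σ0² + 2Dt.
* **Markov chain.**  The per-state rate equations are checked against the
  chain's generator matrix; long fixed-ligand integrations against its
  null-space stationary distribution; zero-ligand decay against a
  tight-tolerance LSODA integration.
* **Reductions and conservation.**  With all valences zero the PNP and D
  trajectories coincide to solver tolerance; closed-domain runs conserve
  each species' content to round-off; with the opening active, vesicle +
  cleft + extracellular glutamate is conserved.

## Desk-scale runs and what they show

The shipped comparison (`generate_fixture("coarse3d")`) uses the coarse
mesh (≈ 6.4e3 cells, ≈ 38k coupled unknowns), dt = 0.02 ms, 1 ms simulated
— enough to cover the AMPA current peak (~0.65 ms at this resolution).  The
paired runs take roughly ten minutes on one CPU, the great majority in the
PNP Newton solves.  On this mesh the D model's cleft-center glutamate at
0.5 ms exceeds the PNP value by ≈ 40%, and the PNP current peak is ≈ 9%
larger in magnitude than the D peak; the qualitative flux pattern (both
Na+ fluxes toward the cleft center, K+ diffusion out vs drift in, both
Glu- fluxes outward, Ca2+/Cl- redistributed by drift alone) is reproduced.
Desk-scale resolution under-resolves the ~1 nm Debye layers and the lateral
concentration gradients, so the headline percentages carry
discretization error of order tens of percent of themselves; fully
converged fields would need meshes (and run times) orders of magnitude
larger, which is why verification rests on the property suite above rather
than on field-level agreement.

## Known limitations

Idealized flat geometry (no membrane curvature or cleft-width variation);
no fixed membrane surface charges; a single release event with no
repriming; continuum mean-field concentrations (a 4 nm opening passes
discrete molecules in reality); AMPA receptors are Na+/K+ selective only
(no Ca2+ permeability) and the gating scheme has no modal subconductance
states; the D model shares the PNP initial state and geometry, differing
only in the governing operator.
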