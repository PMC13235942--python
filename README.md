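# cleftpnp

Electrodiffusion in the synaptic cleft: a finite-volume simulator that
solves the fully coupled Poisson–Nernst–Planck (PNP) system and the pure
diffusion (D) model on a 3D cuboid synapse — vesicular glutamate release,
five ionic species (Na⁺, K⁺, Ca²⁺, Cl⁻, Glu⁻), and Markov-gated AMPA
receptors — and quantifies how much neglecting electrical drift changes the
predicted concentrations and receptor current.

## Who this is for

Computational neuroscientists and biophysical modelers who describe
neurotransmitter and ion dynamics in nanoscale extracellular spaces.
Diffusion-only models are the common default for the cleft; this package
solves the full electrodiffusion problem alongside the diffusion problem on
identical meshes and schedules, so the error of the diffusion approximation
can be measured directly.

## The model

Concentrations evolve by the Nernst–Planck equation

```
∂[k]/∂t = ∇·( D_k ∇[k] + D_k z_k e/(k_B T) [k] ∇φ ),
```

with the potential determined by the Poisson equation
`∇·(ε_r ε_0 ∇φ) = −F Σ_k z_k [k]`.  The pure-diffusion model keeps only
`∂[k]/∂t = ∇·D_k∇[k]`.  A 40 nm vesicle loaded with 150 mM glutamate opens
into the 15 nm cleft through a 4 nm pore at t = 0; glutamate gates 200
AMPA receptors (7-state Markov scheme) on a 140 nm square of the
postsynaptic membrane, whose Na⁺/K⁺ fluxes
`J_k = N/(F w_a²) · g_k · o · (v − v0_k)` feed back on the ion fields.
Both models are advanced with implicit Euler (dt = 0.02 ms); the PNP system
is solved monolithically with a damped Newton iteration.  See
`docs/methods.md` for the discretization, solvers and verification oracles.

## Worked example

```python
import cleftpnp as cp

config = cp.generate_fixture("coarse3d")      # default synapse, desk-scale mesh
pnp, d, report = cp.run_comparison(config, t_eval=0.5)

print(f"[Glu-] excess of D over PNP at cleft center: "
      f"{report.excess_percent('Glu-'):.1f} %")
print(f"peak I_AMPA: PNP {report.peak_current_a:.3f} nA, "
      f"D {report.peak_current_b:.3f} nA "
      f"({report.peak_excess_percent:.1f} % more negative in PNP)")
```

On the desk-scale mesh (≈6 400 cells, 1 ms simulated, ~10 minutes on one
CPU) this prints

```
[Glu-] excess of D over PNP at cleft center: 40.3 %
peak I_AMPA: PNP -0.201 nA, D -0.184 nA (9.0 % more negative in PNP)
```

meaning the diffusion-only model overestimates cleft-center glutamate at
0.5 ms by ~40 % — electrical drift expels the negatively charged
transmitter from the cleft — while the peak receptor current differs by
only ~9 % because the electrodiffusive effects on the current partially
cancel.  `report.conc_ratio` holds the per-species D/PNP ratios and
`report.profiles` the center-line profiles of all fields.

The same workflows are available from the shell:

```
cleftpnp dump-defaults > scenario.yaml     # full editable parameter pack
cleftpnp compare --config scenario.yaml --out results/
cleftpnp sweep --axis vesicle_glu --values 100,150,200 --out sweep/
cleftpnp demo1d                            # 1D equilibrium illustration
```

Snapshots are written as plain-text VTK rectilinear grids and time series
as CSV; every run writes a manifest with a config hash for exact reruns.
The pipeline contains no random number generation — identical configs give
identical outputs.

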