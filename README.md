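# nanodozer

Brownian-dynamics simulation and nonlinear moving-boundary diffusion
modelling of a channel-confined DNA molecule squeezed by a sliding gasket
piston ("nanodozer") and then released.

## The problem

In nanofluidic experiments a single DNA molecule confined in a channel of
width D (de Gennes / extended de Gennes regime, persistence length
L_p ≤ D) is compressed along the channel axis by a sliding piston and
subsequently allowed to relax. The observable is the axial concentration
profile c(x, t): compression launches a shockwave of enhanced
concentration at the piston edge that propagates down the chain until a
linearly ramped steady state forms; release lets the profile decay
through parabola-like shapes back to the flat equilibrium plateau c₀.

`nanodozer` provides both halves of the standard analysis of this
experiment, for people simulating confined polymers or fitting
experimental nanochannel profiles:

* a coarse-grained **bead-spring Langevin simulator** (WCA excluded
  volume, FENE bonds, κ(1 − cos θ) bending; underdamped Langevin dynamics
  with exact-friction stochastic-Verlet integration; analytic or
  bead-built channel walls and a moving impermeable gasket),
* a **nonlinear moving-boundary diffusion model** for c(x, t):

      ∂c/∂t = ∂/∂x [ D_c(c) ∂c/∂x − cV ],   D_c = D₀ (c/c₀),

  on a moving domain [x₁(t), x₂(t)] whose free edges obey a force balance
  with the osmotic pressure Π = Π₀[−c₀/c + (c/c₀)²] against an edge
  friction (dimensionless α = ξD₀/(Π₀D²r₀)), halting relaxation at c₀;
* the **fitting layer** connecting them: concentration-profile binning,
  Gaussian edge-broadening convolution (distinct σ per edge), extraction
  of D₀ from the steady ramp slope (reduced slope = V/V₀ with
  V₀ = D₀/r₀), least-squares α fitting, and parabolic retraction-profile
  fits.

In reduced variables (u = c/c₀, x/r₀, t/τ with τ = r₀²/D₀) the steady
compression profile is a linear ramp of slope exactly V/V₀ — the property
that lets a single steady profile calibrate D₀.

## Worked example

Equilibrate a scaled-down chain (N = 64 beads, channel D = 16), then
solve the diffusion model at the corresponding reduced speed:

```python
import numpy as np
from nanodozer import (RunPlan, equilibrate, NPDEParams,
                       solve_compression, steady_state_ramp)

plan = RunPlan(n_beads=64, base_seed=3, max_equil_snapshots=2000,
               equil_sample_snapshots=100)
state, eq = equilibrate(plan)
print(f"r0 = {eq.r0:.1f} bond lengths, c0 = {eq.c0:.2f}")

p = NPDEParams(Do=0.74, r0=235.0, V=0.05, alpha=0.07)
print(f"tau = {p.tau:.0f} snapshots, V/Vo = {p.vbar:.1f}")
ramp = steady_state_ramp(p)
slope = np.polyfit(ramp.grid, ramp.u, 1)[0]
print(f"steady ramp slope = {slope:.2f}")
```

prints

```
r0 = 15.7 bond lengths, c0 = 4.34
tau = 74628 snapshots, V/Vo = 15.9
steady ramp slope = 15.88
```

The first line is the equilibrium extension of the confined chain (in
units of the mean bond length 0.97 σ) and the plateau concentration — the
two normalization scales of the reduced description. The second line is
the diffusive time scale τ = r₀²/D₀ of a full-scale chain (r₀ = 235 bl)
at cooperative diffusivity D₀ = 0.74 bl²/snapshot, and the reduced gasket
speed. The last line confirms the analytic steady state: the ramp slope in
reduced variables equals V/V₀.

A command-line surface wraps the stages for shell use
(`nanodozer equilibrate|compress|retract|npde|fit|report`, each driven by
a YAML run configuration; see `nanodozer --help`).

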