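# Methods

`nanodozer` models the nonequilibrium dynamics of a single long polymer
(double-stranded DNA at scales above its persistence length) confined in a
nanochannel and compressed along the channel axis by a sliding gasket
piston, then released. It couples two descriptions: a coarse-grained
Brownian-dynamics (BD) simulator that resolves chain conformations, and a
one-dimensional nonlinear moving-boundary diffusion model (NPDE) for the
axial concentration profile c(x, t), which is cheap enough to fit both
simulation and experimental profiles. The fitting layer maps one onto the
other.

## Bead-spring model and force field

The chain is N beads of diameter σ_b connected by springs, with the
semiflexible Kremer–Grest Hamiltonian:

* **Excluded volume**: the purely repulsive cut-and-shifted Lennard-Jones
  (WCA) potential, `U = 4ε[(σ_b/r)^12 − (σ_b/r)^6] + ε` for
  `r ≤ 2^(1/6) σ_b`, zero beyond, acting between *all* bead pairs
  (bonded pairs included, the standard convention for this model).
* **Bonds**: FENE springs `U = −(k R₀²/2) ln(1 − r²/R₀²)` between
  consecutive beads. A bond reaching R₀ is a hard error (the parameter set
  is chosen so this never happens in healthy runs; silently capping forces
  would mask chain crossing).
* **Bending**: `U = κ(1 − cos θ)` on consecutive bond pairs, giving a
  persistence length `L_p = κ/k_B T` in the continuum limit.

Reduced units: lengths in σ_b, energies in ε, k_B = 1, bead mass m = 1.
Defaults (validated, stable, non-crossing): ε = 1, k = 30, R₀ = 1.5,
κ = 3.2, γ = 0.7, T = 1.2, dt = 0.01. The mean equilibrium bond length is
bl ≈ 0.97 σ_b, which serves as the length unit of the analysis layer; one
"snapshot" is 1000 integration steps (10 reduced time units).

The confining channel has a square D×D cross-section (y, z ∈ [0, D]),
translationally invariant and effectively infinite along −x. By default
walls and the gasket are smooth planes with a WCA interaction on the
perpendicular distance ("analytic" mode): the physics depends only on
purely repulsive confinement, and planar walls realize an infinite channel
exactly. A "beads" mode (immobile WCA particles on a square lattice of
spacing σ_b, gasket likewise) is retained for fidelity cross-checks; the
lattice spacing ≤ σ_b makes the gasket impermeable, which the test suite
drives directly. D is interpreted wall-plane to wall-plane, so the
accessible width is slightly smaller than D.

## Langevin integration

The equation of motion `m r̈ = −∇U − γv + R` is integrated with symmetric
splitting schemes in which the friction/noise (Ornstein–Uhlenbeck) part is
integrated *exactly* over (half) steps: the default `gunsteren_berendsen`
scheme is the stochastic-Verlet variant O(dt/2) B(dt/2) A(dt) B(dt/2)
O(dt/2); `baoab` is provided as an independent cross-check. Per component
the noise obeys the fluctuation–dissipation relation
`⟨R(t)R(t′)⟩ = 2γk_BT δ(t−t′)`; the exact OU updates use variance
`(k_BT/m)(1 − e^{−2γΔ/m})` per (half-)step Δ. Free-particle velocity
statistics are exact at any dt; configurational errors are O(dt²). The
contract is validated against closed forms: exponential velocity decay at
T = 0, the Einstein relation D = k_BT/γ, harmonic-trap variance k_BT/k,
and equipartition.

Noise is drawn in bulk (PCG64) per 1000-step segment in fixed bead order,
so trajectories are bit-reproducible given the run seed. The production
force loop is a numba kernel with a cell list (cell size = WCA cutoff,
lazily invalidated by a stamp array); it is validated against the pure
numpy reference implementation and finite-difference gradients to 1e-6.

## Squeezing protocol

1. **Equilibrate**: gasket-free confined dynamics from a helical initial
   conformation wound to ≈ 30% of the contour length (near the expected
   confined density, shortening the transient; the stationarity test, a
   sliding-window drift fit with a 2-SE noise clause and a minimum burn-in,
   decides equilibration — the initial condition does not bias the
   measured equilibrium). The equilibrium extension r₀ (in bl) and the
   plateau concentration c₀ (contour per unit length, from the central 60%
   of the COM-aligned average profile) are the normalization scales. The
   extension autocorrelation time is long (~100 snapshots at N = 256), so
   r₀ is averaged over several hundred snapshots.
2. **Compress**: the gasket starts just beyond the chain's +x edge and
   slides at −v_push (bond lengths per snapshot). Steady state is declared
   when, over a trailing window, the fitted drifts of XCOM, x_min and
   x_max match the gasket speed within tolerance *plus the statistical
   resolution of the windowed fit*, two disjoint windows agree on the mean
   extension within their own block-estimated noise, and the extension
   drift is below noise. Because the late transient decays below any
   finite-window noise floor, quantitative steady-state analyses use fixed
   run lengths sized from the diffusive settling time τ(w/r₀)² of the
   compressed region and average only trailing snapshots.
3. **Retract**: the gasket reverses at 4·v_push; once it outruns the chain
   by more than the WCA cutoff it is dropped from force evaluation (no
   physical effect, saves cost). Profiles relax back to the flat plateau.

Concentration profiles are binned by apportioning each bond's length to
x-bins (width 2 bl) in proportion to the overlap of the bond's
x-projection — the unbiased reading of "summing bond lengths in bins" that
conserves contour exactly per frame. Compression profiles are recorded in
the gasket frame; retraction profiles in the lab frame and COM-aligned
before averaging (mass-conserving continuous shift via the cumulative).

## Nonlinear moving-boundary model

In reduced variables u = c/c₀, X = x/r₀, s = t/τ with τ = r₀²/D₀ and
V₀ = r₀/τ:

* bulk: `∂u/∂s = ∂_X [u ∂_X u − u V̄]` (cooperative diffusivity
  D_c = D₀·c/c₀; V̄ = V/V₀ is the compression speed, active only while the
  gasket drives the chain — compression is solved in the gasket frame with
  the gasket-side edge pinned and zero flux through it);
* edges: force balance `ξ dx_i/dt = ∓ΠD² + ξV` with the osmotic pressure
  `Π = Π₀[−c₀/c + (c/c₀)²]` (zero at c₀, so relaxation halts at the
  plateau); after nondimensionalization only the combination
  α = ξD₀/(Π₀D²r₀) survives. Signs are fixed by the physics: pressure
  drives each edge outward; the stationary edge condition
  `Π̃(u₁) = αV̄` with mass conservation yields the analytic steady state —
  a linear ramp of reduced slope exactly V̄, which the solver reproduces
  to 0.1%. The flux balance at a free edge, `u·ẋ_i = J`, is the
  mass-conservation condition through a moving boundary and enters as the
  boundary flux.
* retraction: V = 0 once the gasket detaches (it retracts faster than the
  chain expands), both edges free.

Numerics: the moving domain [x₁, x₂] is mapped to the unit interval;
a conservative finite-volume scheme (M = 200 cells, central fluxes,
explicit Euler with diffusive-CFL-limited adaptive steps, edge values by
linear extrapolation, outflow-limited edge cells) advances the cell
masses. Boundary faces carry exactly zero relative flux, so total mass is
conserved to machine precision; negative concentrations abort rather than
clamp. Self-convergence is first order or better; M = 200 is converged to
< 0.5% in L2 for all cases used.

The free energy `f/k_BT = A[(r_b − r)/r₀ + (r₀/r)²]` of the extended
de Gennes regime is provided for diagnostics only; the dynamics uses Π
directly (the constants A, r_b have no operational role).

## Thermal broadening and fitting

Extension fluctuations broaden the sharp NPDE edges; this is modeled by
convolving model output with a unit-integral Gaussian whose width σ may
differ between the gasket-adjacent and far edges (σ varies linearly in x
between the edge values; each source cell spreads with its local σ and a
discretely normalized kernel, so mass is preserved exactly and σ → 0 is
the identity). σ is fitted to the t = 0 profile: a broadened box for
compression (two σ values), a broadened ramp for retraction (one σ).

* `extract_Do`: the reduced steady-ramp slope m gives D₀ = V·r₀/m. The
  fit uses the rising flank only (points past the profile peak belong to
  the broadened gasket edge).
* `fit_alpha`: deterministic bounded 1-D search (Brent on log α over
  [1e-3, 10]) minimizing the summed squared difference between convolved
  model profiles and data profiles over all supplied times.
* `fit_parabola`: least squares of `max(0, c_m[1 − ((x−x_c)/w)²])` ⊛
  Gaussian with multi-start width initialization — the
  fluctuation-robust estimate of the retraction profile maximum.
* `fit_speed_exponent`: log–log slope of steady extension vs speed,
  optionally restricted to the largest speeds.

All fitters are validated by parameter recovery on self-generated data
(α to 1%, σ to 5%, D₀ to 2%, parabola amplitude to 3% under 5% noise).

## Persistence-length estimator

`L_p` is estimated from bond-vector correlations ⟨cos θ(s)⟩ by a
zero-intercept fit of ln⟨cos θ(s)⟩ = −s·bl/L_p over the contiguous
separations with correlation above 0.25. The high floor is deliberate:
excluded volume adds a slowly decaying large-s tail on top of the local
exponential decay (visible as a plateau of ~0.13 at κ = 3.2), and the
persistence length is defined by the initial decay. With this estimator
the BD chains obey L_p = κ/k_BT within ~10% for κ ∈ [2, 8] — measured
values sit a few percent below the continuum prediction (discrete-chain
correction) at large κ and a few percent above at small κ (residual
excluded-volume stiffening), consistent with the model being applied
outside the strict worm-like-chain limit. Free chains for these
measurements start from equilibrium self-avoiding worm-like-chain draws
(bond angles from the exact bending Boltzmann weight, grown with clash
rejection), so only local relaxation precedes sampling.

## Scaled study conditions

Quantitative BD experiments in the test suite run at reduced size, chosen
so the full suite completes on a desktop core:

* Bond-length calibration: N = 64, 300 snapshots equilibration + 200
  sampling, κ ∈ {0, 3.2}.
* Integrator contract: 64–128 independent particles / free chains of
  N = 128, 1e5–2e5 steps, 8 seeds for diffusion, 3 replicas per κ for L_p.
* Squeezing study: N = 256, D = 16, one long equilibration (600-snapshot
  sampling window), compression at v_push ∈ {0.025, 0.05, 0.1, 0.2}
  bl/snapshot — a factor-8 span around the reference speed 0.05 — with
  fixed durations (3000/1600/1300/1000 snapshots) sized from the diffusive
  settling time, trailing 40% of snapshots averaged.

At this scale the chain's fractional extension r₀/((N−1)·bl) ≈ 0.23
matches the full-scale N = 1024 value (extension is linear in contour in
the de Gennes regime), and the ramp-extracted cooperative diffusivity is
N-independent (a local transport coefficient); the full-scale claims are
therefore checked through these transferable forms. Full-scale runs
(N = 1024, ensembles of 10, speeds down to 0.005) use the same code paths
and are an overnight-desktop workload.

Measurement conventions at this scale, dictated by the ~±10% extension
fluctuations of a short chain with O(100-snapshot) correlation times:

* steady extension = trailing time average; adjacent speeds are compared
  with a ±1.5 bl noise allowance when asserting monotonicity;
* steady ramp slope for the linearity-in-speed check: line fit to the
  central rising flank of the COM-aligned trailing-average profile;
* D₀: broadened-ramp model fit at the two lower speeds (at high speeds
  σ becomes comparable to the ramp width and slope/σ are no longer
  separately identifiable; at low speeds the window fit is biased by
  extension-fluctuation flattening, the model fit is not);
* shock propagation: integral metrics (centroid and extent of the excess
  density above the plateau) on block-averaged profiles, robust where
  threshold crossings are noise-dominated.

## What the synthetic conditions do and do not show

The generator-level conditions emulate the physical study design (chain in
the de Gennes/extended de Gennes regime, L_p/D ≤ 1, impermeable driven
gasket, free relaxation). They do not emulate: hydrodynamic interactions
(free-draining friction only), electrostatics (assumed screened into the
effective bead diameter), sequence heterogeneity, or knotting dynamics.
Passing tests therefore demonstrate the internal consistency of the
BD + NPDE pipeline and the transferability of its reduced description —
not agreement with any specific experimental DNA dataset.

## Known limitations

* The NPDE edge-friction α is purely phenomenological; compression and
  retraction generally need different values.
* A single constant σ per edge understates broadening at late retraction
  times (fluctuations grow as concentration falls); refitting σ to
  long-time profiles is the pragmatic alternative, exposed via the fit
  window.
* The window-averaged steady profiles of short chains are flattened by
  extension fluctuations; slope estimators must be chosen per regime (see
  above).
* Stiff chains (L_p/D > 1, the deflection regime) need a different edge
  free energy and are out of scope.
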