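# Methods

This note records the model, the discretisation, the numerical choices and
the design decisions behind `stokesflow`, together with what the synthetic
benchmarks do and do not demonstrate.

## Physical model

The observable intracellular material is modelled as a single-phase
incompressible Newtonian fluid. At cellular scales the Reynolds number is of
order 10⁻⁵, so inertia and advection of momentum are negligible and the flow
obeys the Stokes equations on the cell interior Ω with boundary Γ:

    ∇p − μ∇²u = f   in Ω
        ∇·u   = r   in Ω        (r ≡ 0 in 3D)
          u   = g   on Γ

with viscosity μ (default 1 Pa·s, a standard cytoplasm value), body-force
density f (all forces other than viscous drag and the pressure gradient,
e.g. actomyosin contractility), membrane velocity g, and — in 2D only — an
apparent divergence r capturing material that enters or leaves the focal
plane. Elasticity is neglected: at frame intervals of ~0.1–1 s the
viscoelastic relaxation of cytoplasm is essentially complete, so the purely
viscous model is a reasonable first approximation. Organelles (nucleus,
vesicles) are not modelled separately.

Unit system: lengths in μm, time in s, pressure in Pa. In this system f
carries Pa/μm. For a 2D result interpreted as a slab of depth h μm the
in-plane force surface density is f·h; `ForceField.to_nN_per_um2` performs
the conversion (1 Pa/μm over a 1 μm slab = 10⁻³ nN/μm²).

## The inverse problem

Between consecutive frames I₁, I₂ the brightness-constancy relation
I(x + uΔt, t + Δt) = I(x, t), linearised in the displacement uΔt, gives the
data term

    J_data(u) = ∫Ω (∇I₂ · uΔt + (I₂ − I₁))² dΩ,

and the controls are penalised by

    J_reg(f, g, r) = α∫Ω‖f‖² dΩ + γ∮Γ‖∇_Γ g‖² dΓ + η∫Ω‖∇r‖² dΩ,

where ∇_Γ is the tangential gradient along Γ. The ‖∇r‖² form is the default;
`r_mode="value"` switches to an ‖r‖² penalty for regimes where r itself is
expected to be small. The minimisation of J_data + J_reg subject to the
Stokes constraint is feasible-path: the state (u, p) is eliminated by an
exact solve at every evaluation, so each iterate satisfies the constraint to
solver tolerance and the cost is a convex quadratic function of the
controls.

Implementation detail with practical consequences: the image gradient in
the data term uses both frames, G = (∇I₁ˢ + ∇I₂ˢ)/2, after smoothing both
frames with the same Gaussian kernel (σ = 1 px default). Smoothing both
frames keeps the linearised residual consistent for any flow that the
kernel commutes with (exactly so for translations), and the symmetric
two-frame gradient is second-order accurate in the displacement and halves
the gradient-noise variance.

## Discretisation

* **Mesh.** The cell mask's 0.5 iso-contour is extracted, smoothed by 3
  Laplacian passes (a pixelated contour otherwise imprints oscillations on
  g), resampled at the target edge length (default 2 px), filled with a
  hexagonal interior lattice and Delaunay-triangulated, clipping triangles
  whose centroid leaves the polygon. The mesh measure is required to match
  the mask measure within 3%. 3D masks are split voxel-wise into six
  tetrahedra (Kuhn decomposition).
* **Elements.** Taylor–Hood: continuous piecewise-quadratic velocity,
  continuous piecewise-linear pressure (inf-sup stable); f and r on the
  linear vertex space; g on the quadratic trace space of Γ. Dirichlet data
  is imposed strongly on boundary velocity nodes.
* **Gauge and compatibility.** A pure-Dirichlet Stokes problem fixes p only
  up to a constant and requires ∮Γ g·n dΓ = ∫Ω r dΩ. One scalar Lagrange
  multiplier pair enforces zero-mean pressure and absorbs any flux mismatch
  as a uniform divergence. In 2D the multiplier is folded back into the
  reported r as a constant shift (free under the ‖∇r‖² penalty), so
  ∮u·n dΓ = ∫r dΩ holds exactly for every reported solution. In 3D, where r
  does not exist, incompatible g is either rejected (`strict`) or projected
  by removing a constant normal flux (`project`, default).
* **Quadrature.** Degree-4 rules (6-point triangle, 11-point tetrahedron),
  exact for all mass/stiffness products of the element pair; the image data
  is sampled at the same quadrature points by bilinear interpolation.
* **Linear solves.** One sparse LU factorisation per mesh
  (`scipy.sparse.linalg.splu`, symmetric-mode minimum-degree ordering,
  roughly halving fill relative to the default) is reused for every forward
  and adjoint (transposed) solve.

Verification: on the manufactured sinusoidal solution the velocity L2 error
converges at third order and the pressure at second order under uniform
refinement, the textbook Taylor–Hood rates; `scripts/acceptance.py`
recomputes the orders on 8/16/32 unit-square meshes.

## Optimisation

The reduced gradient is assembled exactly for the discretised problem: one
adjoint solve with the transposed factorisation, plus the analytic
derivative of the regulariser (verified against central finite differences
to < 10⁻⁴ relative error; since the cost is quadratic, the agreement is
limited only by round-off). The default optimiser is L-BFGS: the functional
is convex quadratic, so L-BFGS reaches the same stationary point as plain
gradient descent in far fewer forward/adjoint solves. Plain steepest
descent with Armijo backtracking (and a Barzilai–Borwein initial step) is
available as `optimizer="steepest"`. Convergence is declared when the
relative cost decrease over 5 iterations falls below 10⁻⁴ (default), with at
most 200 iterations per scale.

Two accelerations matter in practice:

* **Block preconditioning.** The Hessian curvature differs by orders of
  magnitude between the f, g and r blocks. Because the gradient is affine in
  the controls, probing a few unit vectors yields exact Hessian diagonal
  entries; the median per block defines a diagonal scaling under which
  L-BFGS converges several times faster. The probes are deterministic.
* **Warp refinement.** After each minimisation the displacement estimate is
  used to warp I₂ backward and the data term is re-linearised about it
  (controls keep describing the *total* flow, so the reported p, f, g, r
  always belong to the full velocity). Two refinement passes per scale
  (default) remove the first-order bias of the frozen-gradient
  linearisation; on a noiseless 0.5 px translation they reduce the mean
  velocity error from ~10% to ~0.3%.

Large displacements are handled coarse-to-fine on a Gaussian pyramid
(factor 2, anti-aliasing σ = 0.8·factor): the coarse solution's displacement
warps the next level's I₂, and the controls are prolonged as a warm start.
`n_scales=1` reduces exactly to the single-scale path.

## Regularisation weights

When α, γ, η are not given they are balanced automatically: a pilot
minimisation with unit weights is run to convergence, and each weight is
rescaled so its term equals a fixed fraction (default 10%) of J_data at the
pilot iterate. The procedure is deterministic and invariant to intensity
rescaling of the input (the reg/data ratio at the pilot is the fraction by
construction). Known limitation: like any fraction-of-misfit rule it inherits
the pilot's misfit scale, and the resulting weights produce a few percent of
Tikhonov shrinkage on controls whose truth has nonzero penalty (see below).

## Synthetic benchmarks: what they emulate and what they do not

The generator renders speckle textures (Gaussian blobs of σ = 1.5 px at
Poisson positions, density 2 μm⁻², amplitudes uniform in [0.5, 1.5])
emulating short fluorescent filaments in suspension, restricts them to the
cell domain, advects them along analytic flows by backward characteristic
tracing (midpoint substeps, a single final interpolation, so a uniform
integer-pixel shift is exact and brightness constancy holds by
construction), and applies Poisson noise (~100 photons at peak) plus
Gaussian read noise (1% of peak) — a plausible EMCCD regime. Defaults mirror
the imaging setup the method targets: 0.16 μm pixels, 0.4 s frame interval,
cell radius 8 μm.

Analytic cases (all exact Stokes solutions): uniform translation, rigid
rotation, planar Poiseuille channel flow with its −8μU/H² pressure
gradient, a sinusoidal manufactured solution with analytic body force, and
a uniform radial source u = r₀(x−c)/2 with r ≡ r₀ whose material disk grows
as dR/dt = r₀R/2.

What passing these benchmarks does **not** show about real data: the
generator satisfies brightness constancy exactly (no photobleaching, no
z-blur or PSF, no background fluorescence), its flows are noise-free and
exactly Stokes, and its masks are exact. Real recordings violate all of
these to some degree; the benchmarks validate the estimator, not the model
assumptions.

## Recovery accuracy at the default conditions

Measured by `scripts/acceptance.py` (seed 1, one CPU):

* Translation (0.5 px/frame, noisy): mean velocity error ~3–5%, relative L2
  velocity error ~9%. The recovered force stays 1–2 orders of magnitude
  below the μU/L² viscous scale *in absolute terms*, but noise-driven
  fluctuations keep mean‖f‖ at roughly 10–30% of that scale, and the nodal
  pressure range at a few times μU/L — far above the noise-free ideal of
  zero. Both residuals are noise-floor effects: they persist at the exact
  minimiser across a wide sweep of regularisation weights (strengthening γ
  or α beyond the auto-balanced values first flattens, then biases, the
  velocity). A noise-free pair reduces both by an order of magnitude.
* Poiseuille channel: transverse profile parabolic with R² > 0.999,
  channel width recovered within ~10%, recovered pressure correlates with
  the analytic linear drop at Pearson r ≈ 0.99.
* Large displacement (5 px/frame): three pyramid scales recover the motion
  to ~0.5% mean-velocity error, while a single scale misses it by ~45%
  (both arms run without warp refinement so the comparison isolates the
  pyramid mechanism; the symmetric two-frame gradient lets even the
  single-scale estimator track part of a 5 px motion, which a frozen
  one-frame gradient would miss almost entirely).
* Divergence source: the net area change Δt∫r dΩ is recovered with ~8–11%
  underestimation. The systematic part (~8%, present without noise) is
  Tikhonov shrinkage: a radial boundary velocity has nonzero ∮‖∇_Γg‖² (its
  direction rotates with curvature 1/R), so the γ-penalty trades a few
  percent of expansion against data misfit. The flux identity
  ∮u·n dΓ = ∫r dΩ holds to machine precision by construction.
* Zero motion: identical frames return exactly zero velocity, force and
  pressure (the optimiser starts at the global minimum and the gradient
  vanishes identically).

## Analytics

* Streamlines: adaptive RK45 (`solve_ivp`) on the piecewise-linear
  interpolant of the quadratic velocity; stops at Γ or a maximum arc length.
* Vorticity: curl of the quadratic velocity projected onto the vertex space
  by a mass-matrix solve (exact for rigid rotation: 2ω).
* Poiseuille fit: least-squares parabola; the width is the distance between
  its real roots, flagged undefined for degenerate (near-linear) profiles.
* Sigmoid pressure profiles: p = d + a/(1 + e^{−b(s−c)}) on normalised arc
  length, deterministic initialisation (offset/range/half-crossing/quartile
  slope); the linearising transform c − ln(a/(p−d) − 1)/b collapses exact
  sigmoids onto the identity line, and (a, b, c, d) sets are compared by
  standardised PCA + seeded k-means (10 restarts).
* Time series: zero-phase (forward–backward) Butterworth low-pass (order 4,
  cutoff 0.5 Hz defaults; zero-phase because the downstream cross-correlation
  lags would be biased by a causal filter); normalised cross-correlation lag
  with the convention that a positive lag means the first series precedes
  the second; Fourier periodicity by amplitude-ranked *local maxima* of the
  spectrum (plain bin ranking would return two leakage sidelobes of one
  strong component); period histograms fitted by a sum of Gaussians with
  mode-based deterministic initialisation.
* Out-of-plane bookkeeping: V_in = Δt∫_{r>0} r dΩ, V_out = −Δt∫_{r<0} r dΩ
  under the unit-μm slab convention, so V_in − V_out equals the area change
  times 1 μm exactly at quadrature level.
* Darcy estimate: Δp = uνh/l² for cytosol percolating the actin cortex
  (u in μm/s, ν in Pa·s, h and l in μm; the μm factors cancel, giving Pa).

## Known limitations

* Single cell, fixed topology; no division or fusion.
* The viscous (Newtonian) model ignores elasticity and organelle
  heterogeneity; recovered f absorbs whatever the model omits.
* The auto-weight rule is a balancing heuristic, not a statistically
  calibrated choice (e.g. discrepancy principle); its shrinkage bias is
  documented above.
* 3D support covers image handling, voxel tetrahedral meshing and the
  dimension-generic solver/adjoint; the recovery benchmarks and analytics
  target the 2D path, which is where the divergence source r exists.
* Pressure is resolved up to the zero-mean gauge; only pressure differences
  are physical.
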