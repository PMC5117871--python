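# Methods

## The active nematic gel model

The cortical actomyosin layer is described as a thin film of an active
nematic gel flowing along the anterior–posterior (AP) axis. The scalar
nematic order Q(x, t) — positive when filaments align circumferentially,
orthogonal to the flow — evolves by advection, compression-induced
alignment, relaxation toward isotropy, and spatial coupling:

∂ₜQ = −v ∂ₓQ − (β/2) ∂ₓv − Q/τ + (ℓ²/τ) ∂ₓ²Q,

optionally extended by a myosin-coupled active-alignment term
(λ′ c(x)/c₀) Q/τ. During the stationary flow phase, multiplying by τ
gives the linear two-point boundary-value problem

ℓ² Q″ − τ v Q′ − (1 − λ′τ c/c₀) Q = (βτ/2) ∂ₓv,

with Dirichlet values C₁, C₂ at the edges of the fit region. The model is
stated in terms of the products βτ and λ′τ because only those are
identifiable from the steady state; β itself is meaningful only when τ
is. The active term is written in its myosin-weighted form
λ′τ·c/c₀·Q (rather than a bare λQ), with c₀ defined as the spatial mean
of c over the fit region; stability requires 1 − λ′τ c/c₀ > 0 everywhere,
and the solver raises an explicit instability error otherwise.

Assumptions: one-dimensional profiles along the AP axis (the equatorial
band is treated as translationally invariant around the circumference);
the flow field v(x) is an input, never fitted; boundary values are free
parameters because the model is only expected to hold in the central
region where the fields are measured reliably.

## Parameters

| parameter | units | meaning | typical scale |
|---|---|---|---|
| τ | min | relaxation time of nematic order | 0.2–2.5 (below 0.5 is undetectable) |
| βτ | min | flow-alignment coupling × τ | ~0.6 |
| ℓ | µm | alignment length | 1.7–4.7 |
| λ′τ | – | myosin-coupled active alignment | 0–0.34 |
| C₁, C₂ | – | boundary values of Q | ≲ 0.1 |

## Numerics

- **Steady solver.** Centred second-order finite differences on a uniform
  grid, refined internally to a spacing ≤ 0.25 µm (cubic interpolation
  back to the data grid) so that alignment lengths down to ~1.7 µm are
  resolved by several points; one banded (tridiagonal) factorisation
  serves all right-hand sides. The cell Péclet number τ|v|Δx/2ℓ² stays
  below 1 on these grids, so centred advection is stable. An independent
  shooting integrator (adaptive Runge–Kutta plus linear superposition)
  cross-checks the solver in the tests to 1e−4.
- **Dynamic solver.** Backward-Euler steps with advection, diffusion and
  relaxation all in the implicit banded operator using the *same* centred
  stencils as the steady solver, with the compression source explicit.
  This was a deliberate choice over explicit upwinding: first-order
  upwind advection adds O(Δx) numerical diffusion that shifts the
  dynamic fixed point away from the steady solution by ~4e−3 at
  Δx = 0.25 µm, whereas with matching stencils the long-time limit
  coincides with the boundary-value solution to solver precision. A CFL
  guard (Δt·max|v| ≤ Δx) is kept for temporal accuracy.
- **Fitting.** For fixed (τ, ℓ, λ′τ) the steady solution is linear in βτ
  and affine in (C₁, C₂); these three are profiled out exactly by linear
  least squares at every step. The nonlinear search runs over
  (log τ, log ℓ[, λ′τ]) with a trust-region least-squares polish from a
  4×4 log-spaced multi-start grid (τ ∈ [0.05, 10] min, ℓ ∈ [0.5, 10] µm);
  residual ties are broken toward smaller τ. λ′τ is bounded below the
  stability limit.
- **τ detectability.** The flat-residual rule refits the linear
  parameters with τ fixed on a log grid spanning (0, 0.5] min; when the
  residual changes by less than 1% *of the total sum of squares of Q*
  everywhere on that interval, τ is reported only as the bound
  "< 0.5 (n.d.)". Normalising by the total sum of squares (rather than by
  the optimum residual) keeps the rule well defined on noiseless
  synthetic data, where the optimum residual is numerically zero. The
  identifiability scan uses the same normalisation for its flat region.
- **Orientation estimation.** 32 px windows with 16 px stride (≈3 µm at
  0.1 µm/px, matching the alignment length scales); per-window histogram
  equalisation (the empirical-CDF map) for intensity-scale invariance;
  Hann taper; spectral power restricted to spatial periods 4–16 px
  (filament-width scales, excluding illumination gradients and
  near-Nyquist noise); the radially averaged isotropic floor subtracted
  per wavenumber shell before angular binning into 180 one-degree bins.
  Sub-bin accuracy comes from the tensor moments, not peak picking.
- **PIV.** 32 px interrogation windows at 50% overlap, normalised
  cross-correlation within a ±8 px search, three-point Gaussian sub-pixel
  refinement, and a 3×3 neighbourhood median/2-sd outlier rule. Verified
  on advected synthetic meshworks: < 0.1 px error for uniform shifts,
  < 0.2 px RMS for a smooth compressive field.
- **Correlation.** Pearson correlation of the overlapping profile
  segments at each lag (restricted to the central 30 µm), averaged over
  stationary-phase time points; this keeps C ∈ [−1, 1] and pins the
  autocorrelation peak at zero lag. Peak offsets from a Gaussian fit over
  ±5 µm around the discrete maximum. Delays use the absolute mean speed
  over the central interval x ∈ [−10, 0] µm, with first-order error
  propagation from the speed's standard deviation.
- **Ingression.** Small-deformation force balance on the eggshell-
  confined axisymmetric cortex: inward traction t_φφ/R₀ − t_ss·R₀″,
  ingression proportional to the traction excess over its fit-region mean
  baseline, clipped at zero (the cortex cannot move outward through the
  shell). The single fitted scale has a closed-form solution; p₃ can be
  held fixed, zeroed (isotropic control) or optimised with the scale
  profiled. A full nonlinear axisymmetric shape solution was deliberately
  not attempted: outer ingressions are ≲ a few µm against a ~15 µm
  radius, well inside the linear-response regime.

## Synthetic data: what it emulates, and what it does not

The meshwork generator grows filaments by a persistent random walk
(Gaussian per-step direction wander), with only the *initial* direction
drawn from a nematic von Mises distribution ∝ exp(B·cos 2(θ − π/2)); the
growth wander then decorrelates orientation along each filament, which is
what makes the measured order saturate at high B. Filament count (60–120
per 256² image), mean length (40 px, gamma-spread), PSF blur and an SNR
defined as (peak − background mean)/background sd are all controllable,
and every generator takes an explicit integer seed. Embryo profile
cohorts are produced by the steady-state forward model plus i.i.d.
Gaussian noise on Q.

Two canonical condition sets (`nemacortex.studies`) fix the synthetic
study: a cytokinesis-like one (Gaussian-bump flow peaking at 5 µm/min,
compression peak ≈0.7 min⁻¹, τ = 2.34 min, βτ = 0.654 min, ℓ = 1.69 µm,
optionally λ′τ = 0.34 with a 2× myosin band) and a pseudocleavage-like
one (weak tanh-front advection, |v| ≤ 1 µm/min, compression peak
0.4 min⁻¹, τ = 0.2 min, βτ = 0.6 min, ℓ = 4.7 µm). Default cohorts are
10 embryos with Q-noise sd 0.02, matching the scale of profile error
bars in this kind of data. Profiles live on the central 30 µm at 0.25 µm
spacing (121 points); these sizes keep every fit and scan in the
analysis scripts within seconds on one core.

The generators do **not** emulate myosin foci, actin cables or bundling,
photobleaching, curvature of the imaged cortex, 3-D geometry, or any
feedback of alignment on the flow. Passing tests therefore demonstrate
that the estimators and fitters are correct and well conditioned under
the stated noise model — not that real cortical images satisfy the
model's assumptions.

## Degenerate inputs and edge cases

Constant image windows yield the flat angular distribution (undefined
orientation); constant profiles are rejected by the correlation and
onset fits; a flat Q with zero compression raises a degenerate-fit
error; correlation maxima on the lag boundary are refused rather than
extrapolated; the ingression extractor rejects contours outside the
eggshell. Bootstrap with fewer than 100 resamples records an explicit
warning in the result.

## Known limitations

- τ below ~0.5 min is reported only as a bound; this mirrors the physics
  (with weak advection the steady profile barely depends on τ), not a
  solver deficiency.
- The dominant-angle field is defined modulo π; filament polarity is not
  measured.
- Per-window tensor magnitudes on pure noise are biased upward (sparse
  spectral residues after background subtraction); unbiased conclusions
  come from field averages, which the tests check are centred on zero
  for unbiased meshworks.
- The ingression model is linear-response with a rigid shell and a
  mean-traction baseline; absolute tension scales are not identifiable,
  only the shared profile scale and the anisotropy contrast.
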