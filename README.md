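# nemacortex

Quantitative analysis of how compressive cortical flow aligns actin
filaments into a contractile ring in the early *C. elegans* embryo.

During both pseudocleavage and cytokinesis, the actomyosin cortex flows
from the posterior toward the anterior. Where the flow decelerates, the
gel is compressed (compression rate −∂ₓv > 0) and actin filaments rotate
into a circumferential orientation — the seed of the constricting ring.
This package implements the full measurement-and-modelling chain for that
phenomenon, for researchers quantifying cortical mechanics in early
embryos or validating active-gel analyses on synthetic ground truth:

- **nematic order from images** — windowed Fourier spectra of filament
  images reduced to the 2-D nematic tensor (Qxx, Qxy); the scalar order
  parameter is Q = −Qxx, positive for circumferential alignment;
- **flow from images** — particle image velocimetry with sub-pixel peak
  refinement, AP velocity profiles, compression rates, erf-fit onset
  timing and stationary-phase detection;
- **active nematic gel model** — the steady state of

  ∂ₜQ = −v ∂ₓQ − (β/2) ∂ₓv − Q/τ + (ℓ²/τ) ∂ₓ²Q [+ (λ′ c/c₀) Q/τ]

  is the linear boundary-value problem
  ℓ²Q″ − τvQ′ − (1 − λ′τ c/c₀)Q = (βτ/2)∂ₓv, solved with Dirichlet
  boundary values C₁, C₂ and fitted to measured profiles by nonlinear
  least squares with (βτ, C₁, C₂) profiled out exactly. τ is the
  relaxation time of order (min), β the flow-alignment coupling, ℓ the
  alignment length (µm), and λ′τ a myosin-weighted active-alignment
  strength. Bootstrap over embryos gives 68% intervals; identifiability
  scans with boundary-only refits detect when only a bound on τ is known
  (reported "< 0.5 (n.d.)", as for pseudocleavage);
- **correlation and delays** — spatial cross-correlation of compression,
  alignment and ingression profiles during stationary flow; Gaussian peak
  offsets converted to co-moving-frame delays Δt = Δx*/|v̄|;
- **ingression prediction** — an anisotropic active-tension model on the
  eggshell-confined cortex: alignment adds +p₃Q to the circumferential
  tension, and a single shared scale maps the traction excess to the
  outer ingression distance, with the p₃ = 0 isotropic control alongside;
- **synthetic ground truth** — filament meshworks with a controllable
  orientation bias B, image advection under analytic flows, and embryo
  profile cohorts generated by the forward model with known parameters.

## Worked example

```python
import numpy as np
from nemacortex import studies, generate_embryo_dataset, fit_gel_parameters

truth = studies.cytokinesis_truth()          # tau=2.34, beta*tau=0.654, ell=1.69
ds = generate_embryo_dataset(truth, studies.cytokinesis_flow(),
                             noise_sigma_Q=0.02, n_embryos=10, seed=100)
from nemacortex import average_datasets
fit = fit_gel_parameters(average_datasets(ds))
print(f"tau = {fit.tau_report} min, beta*tau = {fit.params.beta_tau:.3f} min, "
      f"ell = {fit.params.ell:.2f} um")
```

prints

```
tau = 2.28 min, beta*tau = 0.645 min, ell = 1.62 um
```

— a 10-embryo cohort with Q-noise 0.02 recovers the generating
cytokinesis-scale parameters to a few percent. The relaxation time sets
how long the gel "remembers" alignment, the coupling βτ how strongly
compression creates it, and ℓ over what distance it spreads.

The numbered drivers under `analysis/` run the whole study on synthetic
data and write their tables to `results/`:

```
01_meshwork_validation.py    orientation estimator vs bias, density, SNR
02_flow_piv_validation.py    PIV and compression-rate accuracy
03_gel_parameter_fits.py     fits, bootstrap intervals, tau identifiability
04_correlation_delays.py     compression->alignment delay estimation
05_ingression_prediction.py  anisotropic-tension ingression fit
```

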