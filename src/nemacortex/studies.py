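"""Canonical synthetic study conditions.

The raw microscopy of the study system is not redistributable, so the
pipeline is exercised end-to-end on synthetic data generated under two
canonical condition sets that mirror the two furrowing stages of the
zygote.  These are the fixed conditions used by the analysis scripts, the
test suite and the acceptance benchmarks; they are not tuning knobs.

* cytokinesis-like: strong anterior-directed flow (peak 5 um/min) whose
  compression peaks at ~0.7 1/min, gel parameters tau = 2.34 min,
  beta*tau = 0.654 min, ell = 1.69 um (the non-RNAi cytokinesis best-fit
  values), optionally with a myosin band (peak 2x baseline) and active
  alignment lambda'tau = 0.34;
* pseudocleavage-like: weak advection (|v| <= 1 um/min) with a central
  compression peak of ~0.4 1/min, beta*tau = 0.6 min, ell = 4.7 um and a
  fast-relaxing gel (tau = 0.2 min, below the 0.5 min detection bound).

Profiles live on the central 30 um of the AP axis at 0.25 um spacing.
"""

from __future__ import annotations

import numpy as np

from .gel import GelParameters
from .synth import FlowProfileSpec, MyosinBandSpec

__all__ = [
    "ap_grid",
    "cytokinesis_flow",
    "cytokinesis_truth",
    "cytokinesis_myosin",
    "cytokinesis_active_truth",
    "pseudocleavage_flow",
    "pseudocleavage_truth",
]


def ap_grid(dx: float = 0.25, half_width: float = 15.0) -> np.ndarray:
    """Uniform AP grid over the central fit region, embryo centre at 0."""
    n = int(round(2 * half_width / dx))
    return np.linspace(-half_width, half_width, n + 1)


def cytokinesis_flow(grid: np.ndarray | None = None) -> FlowProfileSpec:
    """Gaussian-bump flow, peak 5 um/min anterior-directed; the compression
    rate -dv/dx peaks at ~0.7 1/min (peak_velocity / width / sqrt(e))."""
    return FlowProfileSpec(
        shape="gaussian_bump",
        peak_velocity=-5.0,
        width=4.33,
        grid=ap_grid() if grid is None else grid,
    )


def cytokinesis_truth() -> GelParameters:
    """Non-RNAi cytokinesis best-fit material parameters."""
    return GelParameters(tau=2.34, beta_tau=0.654, ell=1.69, C1=0.05, C2=0.05)


def cytokinesis_myosin() -> MyosinBandSpec:
    """Equatorial myosin band peaking at twice the baseline concentration."""
    return MyosinBandSpec(baseline=1.0, amplitude=1.0, center=0.0, width=4.0)


def cytokinesis_active_truth() -> GelParameters:
    """Cytokinesis parameters with myosin-coupled active alignment on."""
    return GelParameters(
        tau=2.34, beta_tau=0.654, ell=1.69, lambda_tau=0.34, C1=0.05, C2=0.05
    )


def pseudocleavage_flow(grid: np.ndarray | None = None) -> FlowProfileSpec:
    """Weak tanh-front flow (|v| <= 1 um/min) with a central compression
    peak of 0.4 1/min (|peak_velocity| / 2 width)."""
    return FlowProfileSpec(
        shape="tanh_front",
        peak_velocity=-1.0,
        width=1.25,
        grid=ap_grid() if grid is None else grid,
    )


def pseudocleavage_truth() -> GelParameters:
    """Pseudocleavage-like material parameters: fast relaxation (tau below
    the 0.5 min detection bound), beta*tau = 0.6 min, ell = 4.7 um."""
    return GelParameters(tau=0.2, beta_tau=0.6, ell=4.7, C1=0.02, C2=0.02)
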