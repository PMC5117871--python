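"""Cortex shape, active tension and furrow ingression.

The mid-plane cortex of the compressed zygote is treated as an
axisymmetric surface of radius r(x) confined by the rigid eggshell of
radius R0(x).  Cortical tension has an isotropic active part proportional
to the local myosin concentration, a viscous part proportional to the flow
gradient (acting along the AP direction), and an anisotropic active part
proportional to the nematic order Q with coefficient p3: aligned filaments
(Q > 0 = circumferential) raise the circumferential tension and lower the
AP tension.  In the small-deformation limit the inward normal traction is

    T(x) = t_phiphi(x) / R0(x) - t_ss(x) * R0''(x) ,

and the outer ingression distance follows linearly from the traction
excess over its confinement-balancing baseline (the fit-region mean),
clipped at zero where the cortex presses against the shell:

    u(x) = global_scale * max(T(x) - <T>, 0) .

A single scalar ``global_scale`` is shared between pseudocleavage and
cytokinesis when fitting, with the isotropic control obtained by imposing
p3 = 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize_scalar

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "ShapeContour",
    "IngressionProfile",
    "TensionCoefficients",
    "TensionProfiles",
    "IngressionFit",
    "extract_ingression_profile",
    "active_tension_profiles",
    "predict_ingression",
    "fit_ingression_parameter",
]


@dataclasses.dataclass
class ShapeContour:
    """Mid-plane cortex radius r(x) and eggshell reference radius R0(x), um."""

    x: np.ndarray
    r: np.ndarray
    R0: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.r = np.asarray(self.r, float)
        self.R0 = np.broadcast_to(
            np.asarray(self.R0, float), self.x.shape
        ).astype(float)
        if self.r.shape != self.x.shape:
            raise InvalidParameterError("r must share the grid of x")
        if np.any(self.r <= 0):
            raise InvalidParameterError("radius must be positive")


@dataclasses.dataclass
class IngressionProfile:
    """Outer ingression distance u(x) = R0(x) - r(x) >= 0, um."""

    x: np.ndarray
    u: np.ndarray


@dataclasses.dataclass
class TensionCoefficients:
    """Coefficients of the cortical tension components (model units).

    active   isotropic active tension per unit myosin (c/c0)
    viscous  AP viscous tension per unit compression rate
    p3       anisotropic active tension per unit nematic order
    """

    active: float = 1.0
    viscous: float = 0.1
    p3: float = 0.5


@dataclasses.dataclass
class TensionProfiles:
    """AP (t_ss) and circumferential (t_phiphi) cortical tension profiles."""

    x: np.ndarray
    t_ss: np.ndarray
    t_phiphi: np.ndarray


@dataclasses.dataclass
class IngressionFit:
    global_scale: float
    p3: float
    rss: float
    rss_isotropic: float
    scale_isotropic: float
    predictions: dict
    predictions_isotropic: dict


def extract_ingression_profile(
    contour: ShapeContour, smooth_sigma: float = 0.0
) -> IngressionProfile:
    """Outer ingression u = R0 - r, clipped at zero, optionally smoothed.

    ``smooth_sigma`` is a Gaussian kernel width in micrometres applied to u.
    Raises when the cortex lies outside the eggshell (r > R0).
    """
    if np.any(contour.r > contour.R0 + 1e-9):
        raise InvalidParameterError("contract violation: r exceeds R0")
    u = np.clip(contour.R0 - contour.r, 0.0, None)
    if smooth_sigma > 0:
        dx = float(np.mean(np.diff(contour.x)))
        u = np.clip(gaussian_filter1d(u, smooth_sigma / dx, mode="nearest"), 0.0, None)
    return IngressionProfile(x=contour.x, u=u)


def active_tension_profiles(
    x: np.ndarray,
    c: np.ndarray,
    dvdx: np.ndarray,
    Q: np.ndarray,
    coeffs: TensionCoefficients,
) -> TensionProfiles:
    """Cortical tension components from myosin, flow gradient and order.

    The isotropic active part (proportional to c/c0) is shared by both
    components; the viscous part adds to the AP component only; the
    anisotropic part adds +p3*Q to the circumferential and -p3*Q to the AP
    component, so circumferential alignment (Q > 0) raises circumferential
    tension.  With p3 = 0 the tension is isotropic up to the viscous term.
    """
    x = np.asarray(x, float)
    c = np.asarray(c, float)
    dvdx = np.asarray(dvdx, float)
    Q = np.asarray(Q, float)
    c0 = float(np.mean(c))
    if c0 <= 0:
        raise InvalidParameterError("myosin concentration must have positive mean")
    iso = coeffs.active * c / c0
    t_ss = iso + coeffs.viscous * dvdx - coeffs.p3 * Q
    t_phiphi = iso + coeffs.p3 * Q
    return TensionProfiles(x=x, t_ss=t_ss, t_phiphi=t_phiphi)


def predict_ingression(
    x: np.ndarray,
    c: np.ndarray,
    dvdx: np.ndarray,
    Q: np.ndarray,
    R0,
    coeffs: TensionCoefficients,
    global_scale: float = 1.0,
) -> IngressionProfile:
    """Small-deformation ingression prediction from tension profiles.

    Computes the inward normal traction t_phiphi/R0 - t_ss * R0'' and maps
    its excess over the spatial-mean baseline linearly (``global_scale``) to
    the outer ingression distance, clipped at zero where the cortex presses
    against the eggshell.  Linear in ``global_scale`` by construction.
    """
    x = np.asarray(x, float)
    R0_arr = np.broadcast_to(np.asarray(R0, float), x.shape).astype(float)
    if np.any(R0_arr <= 0):
        raise InvalidParameterError("non-physical negative or zero radius")
    tens = active_tension_profiles(x, c, dvdx, Q, coeffs)
    if np.allclose(R0_arr, R0_arr[0]):
        curvature = np.zeros_like(x)
    else:
        curvature = np.gradient(np.gradient(R0_arr, x), x)
    traction = tens.t_phiphi / R0_arr - tens.t_ss * curvature
    u = global_scale * np.clip(traction - traction.mean(), 0.0, None)
    return IngressionProfile(x=x, u=u)


def _profiled_scale(datasets: dict, coeffs: TensionCoefficients):
    """Closed-form shared scale minimising the summed rss across stages."""
    num = 0.0
    den = 0.0
    shapes = {}
    for stage, d in datasets.items():
        pred = predict_ingression(
            d["x"], d["c"], d["dvdx"], d["Q"], d["R0"], coeffs, global_scale=1.0
        )
        shapes[stage] = pred.u
        num += float(pred.u @ d["u"])
        den += float(pred.u @ pred.u)
    scale = 0.0 if den == 0 else max(num / den, 0.0)
    rss = 0.0
    preds = {}
    for stage, d in datasets.items():
        u_hat = scale * shapes[stage]
        preds[stage] = IngressionProfile(x=np.asarray(d["x"], float), u=u_hat)
        r = d["u"] - u_hat
        rss += float(r @ r)
    return scale, rss, preds


def fit_ingression_parameter(
    datasets: dict,
    coeffs: TensionCoefficients,
    p3_mode: str = "fixed",
    p3_max: float = 5.0,
) -> IngressionFit:
    """Fit the single shared scale (and optionally p3) to measured ingression.

    ``datasets`` maps stage names (e.g. 'pseudocleavage', 'cytokinesis') to
    dicts with keys x, c, dvdx, Q, u (measured ingression) and R0; both
    stages share one scalar ``global_scale``.  ``p3_mode``:

    * 'fixed' — p3 taken from ``coeffs``; only the scale is fitted;
    * 'zero'  — isotropic model (p3 = 0);
    * 'fit'   — p3 optimised jointly with the profiled scale.

    The isotropic (p3 = 0) control is always reported alongside.
    """
    if not datasets:
        raise DegenerateInputError("no datasets to fit")
    for stage, d in datasets.items():
        missing = {"x", "c", "dvdx", "Q", "u", "R0"} - set(d)
        if missing:
            raise InvalidParameterError(f"{stage}: missing fields {sorted(missing)}")
        d["u"] = np.asarray(d["u"], float)

    if p3_mode == "fit":

        def objective(p3):
            _, rss, _ = _profiled_scale(
                datasets, dataclasses.replace(coeffs, p3=float(p3))
            )
            return rss

        res = minimize_scalar(objective, bounds=(0.0, p3_max), method="bounded",
                              options={"xatol": 1e-6})
        p3_hat = float(res.x)
    elif p3_mode == "zero":
        p3_hat = 0.0
    elif p3_mode == "fixed":
        p3_hat = coeffs.p3
    else:
        raise InvalidParameterError(f"unknown p3_mode {p3_mode!r}")

    fitted_coeffs = dataclasses.replace(coeffs, p3=p3_hat)
    scale, rss, preds = _profiled_scale(datasets, fitted_coeffs)
    scale_iso, rss_iso, preds_iso = _profiled_scale(
        datasets, dataclasses.replace(coeffs, p3=0.0)
    )
    return IngressionFit(
        global_scale=scale,
        p3=p3_hat,
        rss=rss,
        rss_isotropic=rss_iso,
        scale_isotropic=scale_iso,
        predictions=preds,
        predictions_isotropic=preds_iso,
    )
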