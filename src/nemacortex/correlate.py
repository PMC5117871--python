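"""Cross-correlation of AP profiles, peak localisation and delay conversion.

During the stationary flow phase the compression, alignment and ingression
profiles are stationary in the lab frame while material flows through them,
so a spatial offset Dx* between two profile peaks corresponds to a temporal
delay Dt = Dx* / |v| in the frame co-moving with the cortical flow, with v
the mean central flow speed.  Also provides the radial image
autocorrelation used to size myosin foci.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateInputError, FitError, InvalidParameterError

__all__ = [
    "CorrelationCurve",
    "PeakFit",
    "DelayResult",
    "cross_correlate",
    "gaussian_peak_offset",
    "offset_to_delay",
    "radial_autocorrelation",
]

#: Default correlation region: the central 30 um of the embryo.
DEFAULT_REGION = (-15.0, 15.0)

#: Central interval used for the mean flow speed entering delay conversion.
CENTRAL_VELOCITY_REGION = (-10.0, 0.0)


@dataclasses.dataclass
class CorrelationCurve:
    """Normalised spatial cross-correlation C(lag), averaged over time."""

    lag: np.ndarray  # um
    C: np.ndarray
    region: tuple[float, float]
    n_times: int


@dataclasses.dataclass
class PeakFit:
    center: float  # um
    center_sd: float
    amplitude: float
    width: float


@dataclasses.dataclass
class DelayResult:
    """Temporal delay from a spatial peak offset.

    Positive delay means the second field lags the first, i.e. its peak lies
    downstream (anterior-ward, for anterior-directed flow) of the first's.
    """

    offset_um: float
    v_mean: float
    v_sd: float
    delay_min: float
    delay_sd: float


def cross_correlate(
    x: np.ndarray,
    f: np.ndarray,
    g: np.ndarray,
    region: tuple[float, float] = DEFAULT_REGION,
    max_lag: float | None = None,
) -> CorrelationCurve:
    """Mean-subtracted, sd-normalised spatial cross-correlation of f and g.

    ``f`` and ``g`` may be 1-D profiles or 2-D (time x space) stacks sampled
    on the common grid ``x``; 2-D input is correlated row by row (each time
    point of the stationary window) and averaged.  Lags run to +-half the
    region width unless ``max_lag`` narrows them.  A positive peak lag means
    g is shifted toward larger x relative to f.
    """
    x = np.asarray(x, float)
    f = np.atleast_2d(np.asarray(f, float))
    g = np.atleast_2d(np.asarray(g, float))
    if f.shape != g.shape or f.shape[1] != x.size:
        raise InvalidParameterError("f and g must share the grid of x")
    mask = (x >= region[0]) & (x <= region[1])
    if mask.sum() < 5:
        raise InvalidParameterError("region too small")
    dx = float(np.mean(np.diff(x[mask])))
    half = 0.5 * (region[1] - region[0])
    if max_lag is not None:
        half = min(half, max_lag)
    n_lag = int(np.floor(half / dx))
    lags = np.arange(-n_lag, n_lag + 1) * dx

    fs = f[:, mask]
    gs = g[:, mask]
    curves = []
    for frow, grow in zip(fs, gs):
        if frow.std() == 0 or grow.std() == 0:
            raise DegenerateInputError("constant field: correlation undefined")
        c = np.empty(lags.size)
        for k, shift in enumerate(range(-n_lag, n_lag + 1)):
            if shift >= 0:
                a, b = frow[: frow.size - shift], grow[shift:]
            else:
                a, b = frow[-shift:], grow[: grow.size + shift]
            # Pearson correlation of the overlapping segments keeps C in
            # [-1, 1] and pins the autocorrelation peak at zero lag
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                c[k] = 0.0
            else:
                c[k] = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
        curves.append(c)
    return CorrelationCurve(
        lag=lags, C=np.mean(curves, axis=0), region=region, n_times=fs.shape[0]
    )


def gaussian_peak_offset(
    curve: CorrelationCurve, support: float = 5.0
) -> PeakFit:
    """Locate the correlation peak by a Gaussian fit around the maximum.

    Fits amplitude * exp(-(lag - mu)^2 / 2 w^2) + offset over ``+-support``
    micrometres around the discrete maximum.  Raises when the maximum sits
    on a lag boundary (peak not localised inside the window).
    """
    lag, C = curve.lag, curve.C
    i = int(np.argmax(C))
    if i == 0 or i == lag.size - 1:
        raise FitError("correlation maximum at a lag boundary")
    sel = np.abs(lag - lag[i]) <= support
    if sel.sum() < 4:
        raise FitError("too few points around the peak")

    def model(z, amp, mu, width, off):
        return amp * np.exp(-((z - mu) ** 2) / (2 * width**2)) + off

    p0 = [float(C[i] - C[sel].min()), float(lag[i]), support / 2, float(C[sel].min())]
    try:
        popt, pcov = curve_fit(model, lag[sel], C[sel], p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Gaussian peak fit failed: {exc}") from exc
    return PeakFit(
        center=float(popt[1]),
        center_sd=float(np.sqrt(max(pcov[1, 1], 0.0))),
        amplitude=float(popt[0]),
        width=float(abs(popt[2])),
    )


def offset_to_delay(
    offset_um: float, v_mean: float, v_sd: float = 0.0
) -> DelayResult:
    """Convert a stationary peak offset into a co-moving-frame time delay.

    Dt = Dx* / |v_mean|; the uncertainty of the mean speed is propagated to
    first order, sd(Dt) = |Dx*| sd(v) / v^2.  Raises for v_mean = 0 (no
    co-moving frame).
    """
    if v_mean == 0:
        raise InvalidParameterError("v_mean must be nonzero")
    speed = abs(v_mean)
    delay = offset_um / speed
    delay_sd = abs(offset_um) * v_sd / speed**2
    return DelayResult(
        offset_um=float(offset_um),
        v_mean=float(v_mean),
        v_sd=float(v_sd),
        delay_min=float(delay),
        delay_sd=float(delay_sd),
    )


def radial_autocorrelation(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Azimuthally averaged autocorrelation and the characteristic size.

    Returns (r_px, C(r), size_px) where the size is the radius at which the
    normalised autocorrelation first falls below 1/e (linear interpolation
    between radii); for a single Gaussian focus of sd sigma this equals
    2 sigma.  Raises for a constant image.
    """
    img = np.asarray(image, float)
    if np.ptp(img) == 0:
        raise DegenerateInputError("constant image: autocorrelation undefined")
    z = img - img.mean()
    h, w = z.shape
    # zero-padded (linear) autocorrelation, normalised by the overlap count
    F = np.fft.rfft2(z, s=(2 * h, 2 * w))
    acf = np.fft.irfft2(np.abs(F) ** 2, s=(2 * h, 2 * w))
    ones = np.fft.rfft2(np.ones_like(z), s=(2 * h, 2 * w))
    counts = np.fft.irfft2(np.abs(ones) ** 2, s=(2 * h, 2 * w))
    acf = np.fft.fftshift(acf / np.clip(counts, 1.0, None))
    acf /= acf[h, w]

    yy, xx = np.indices(acf.shape)
    r = np.hypot(yy - h, xx - w)
    r_int = r.astype(int)
    r_max = min(h, w) // 2
    sel = r_int <= r_max
    sums = np.bincount(r_int[sel], weights=acf[sel])
    counts_r = np.bincount(r_int[sel])
    C = sums / counts_r
    radii = np.arange(C.size, dtype=float)

    threshold = 1.0 / np.e
    below = np.nonzero(C < threshold)[0]
    if below.size == 0:
        size = float(radii[-1])
    else:
        k = below[0]
        if k == 0:
            size = 0.0
        else:
            c0, c1 = C[k - 1], C[k]
            size = float(radii[k - 1] + (c0 - threshold) / (c0 - c1))
    return radii, C, size
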