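"""Cortical flow measurement: PIV, AP profiles, compression, onset, stationarity.

Coordinate conventions (used package-wide): x in micrometres along the AP
axis with the embryo centre at 0 and anterior negative; anterior-directed
flow therefore has v < 0.  Velocities are in um/min, compression rates in
1/min with the compression rate defined as -dv/dx (positive = compression).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter, uniform_filter
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve
from scipy.special import erf

from .errors import DegenerateInputError, FitError, InvalidParameterError

__all__ = [
    "VelocityMap",
    "StationaryWindow",
    "OnsetFit",
    "piv",
    "velocity_profile",
    "compression_rate",
    "fit_onset_time",
    "detect_stationary_window",
    "intensity_profile",
]


@dataclasses.dataclass
class VelocityMap:
    """PIV vector field on a regular grid of interrogation-window centres."""

    x_px: np.ndarray  # 1-D window-centre columns
    y_px: np.ndarray  # 1-D window-centre rows
    vx: np.ndarray  # 2-D, um/min
    vy: np.ndarray
    quality: np.ndarray  # normalized correlation peak per vector
    valid: np.ndarray  # False where the vector was flagged and replaced
    pixel_size: float
    image_shape: tuple[int, int]

    @property
    def x_um(self) -> np.ndarray:
        return (self.x_px - (self.image_shape[1] - 1) / 2) * self.pixel_size

    @property
    def y_um(self) -> np.ndarray:
        return (self.y_px - (self.image_shape[0] - 1) / 2) * self.pixel_size


@dataclasses.dataclass
class StationaryWindow:
    t_start: float
    t_end: float
    i_start: int
    i_end: int  # inclusive


@dataclasses.dataclass
class OnsetFit:
    """Least-squares fit of v(t) = base + amplitude * erf((t - t0) / width)."""

    t0: float
    width: float
    base: float
    amplitude: float
    cov: np.ndarray
    rss: float


def piv(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window_px: int = 32,
    search_px: int = 8,
    dt: float = 2.0,
    pixel_size: float = 0.1,
    overlap: float = 0.5,
    quality_threshold: float = 0.3,
) -> VelocityMap:
    """Particle image velocimetry between two frames.

    Per interrogation window, the displacement maximising the normalised
    cross-correlation within ``+-search_px`` is refined to sub-pixel accuracy
    by a three-point Gaussian fit of the correlation peak, then converted to
    um/min (``dt`` in seconds).  Vectors whose correlation peak falls below
    ``quality_threshold`` or that deviate from their 3x3 neighbourhood median
    by more than two local standard deviations are flagged invalid and
    replaced by the neighbourhood median.
    """
    a = np.asarray(frame_a, float)
    b = np.asarray(frame_b, float)
    if a.shape != b.shape:
        raise InvalidParameterError("frames must have the same shape")
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    h, w = a.shape
    if window_px > min(h, w):
        raise InvalidParameterError("window larger than frame")
    s = int(search_px)
    stride = max(1, int(round(window_px * (1 - overlap))))
    rows = np.arange(s, h - window_px - s + 1, stride)
    cols = np.arange(s, w - window_px - s + 1, stride)
    if rows.size == 0 or cols.size == 0:
        raise InvalidParameterError("frame too small for window + search margin")

    n_pix = window_px * window_px
    ones = np.ones((window_px, window_px))
    dx_px = np.zeros((rows.size, cols.size))
    dy_px = np.zeros_like(dx_px)
    quality = np.zeros_like(dx_px)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            A = a[r : r + window_px, c : c + window_px]
            A0 = A - A.mean()
            norm_a = np.sqrt((A0**2).sum())
            B = b[r - s : r + window_px + s, c - s : c + window_px + s]
            if norm_a == 0 or np.ptp(B) == 0:
                quality[i, j] = 0.0
                continue
            num = fftconvolve(B, A0[::-1, ::-1], mode="valid")
            s1 = fftconvolve(B, ones, mode="valid")
            s2 = fftconvolve(B * B, ones, mode="valid")
            var_b = np.clip(s2 - s1**2 / n_pix, 1e-12, None)
            ncc = num / (norm_a * np.sqrt(var_b))
            iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
            quality[i, j] = float(ncc[iy, ix])
            dy_px[i, j] = iy - s + _gauss3(ncc[:, ix], iy)
            dx_px[i, j] = ix - s + _gauss3(ncc[iy, :], ix)

    scale = pixel_size / (dt / 60.0)  # px/frame -> um/min
    vx = dx_px * scale
    vy = dy_px * scale
    valid = quality >= quality_threshold

    # neighbourhood-median outlier rule (3x3, 2 sd)
    for comp in (vx, vy):
        med = median_filter(comp, size=3, mode="nearest")
        mean = uniform_filter(comp, size=3, mode="nearest")
        sq = uniform_filter(comp**2, size=3, mode="nearest")
        sd = np.sqrt(np.clip(sq - mean**2, 0, None))
        outlier = np.abs(comp - med) > 2 * sd + 1e-9
        valid &= ~outlier
    med_x = median_filter(vx, size=3, mode="nearest")
    med_y = median_filter(vy, size=3, mode="nearest")
    vx = np.where(valid, vx, med_x)
    vy = np.where(valid, vy, med_y)

    return VelocityMap(
        x_px=cols + window_px / 2,
        y_px=rows + window_px / 2,
        vx=vx,
        vy=vy,
        quality=quality,
        valid=valid,
        pixel_size=pixel_size,
        image_shape=(h, w),
    )


def _gauss3(line: np.ndarray, i: int) -> float:
    """Three-point Gaussian sub-pixel refinement of a correlation peak."""
    if i <= 0 or i >= line.size - 1:
        return 0.0
    cm, c0, cp = line[i - 1], line[i], line[i + 1]
    if min(cm, c0, cp) <= 0:
        denom = cm - 2 * c0 + cp
        return 0.0 if denom >= 0 else float(0.5 * (cm - cp) / denom)
    lm, l0, lp = np.log([cm, c0, cp])
    denom = lm - 2 * l0 + lp
    if denom >= 0:
        return 0.0
    return float(0.5 * (lm - lp) / denom)


def velocity_profile(
    vmap: VelocityMap, y_band: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Band-averaged AP velocity profile (x_um, vx) from a PIV map.

    Invalid vectors are excluded from the average; columns with no valid
    vector in the band are returned as NaN.  ``y_band`` is in micrometres.
    """
    if y_band is None:
        mask = np.ones(vmap.y_px.size, bool)
    else:
        y = vmap.y_um
        mask = (y >= y_band[0]) & (y <= y_band[1])
    if not np.any(mask):
        raise DegenerateInputError("empty y band")
    vx = np.where(vmap.valid, vmap.vx, np.nan)[mask]
    with np.errstate(invalid="ignore"):
        prof = np.nanmean(vx, axis=0)
    return vmap.x_um, prof


def compression_rate(
    x: np.ndarray, v: np.ndarray, smooth_sigma: float = 2.0
) -> np.ndarray:
    """Compression rate -dv/dx (1/min) from a velocity profile.

    The profile is Gaussian-smoothed (``smooth_sigma`` in um, 0 disables)
    and differentiated by centred finite differences.
    """
    x = np.asarray(x, float)
    v = np.asarray(v, float)
    if x.size < 5:
        raise InvalidParameterError("need >= 5 grid points")
    dx = float(np.mean(np.diff(x)))
    if smooth_sigma > 0:
        v = gaussian_filter1d(v, smooth_sigma / dx, mode="nearest")
    return -np.gradient(v, x)


def fit_onset_time(t: np.ndarray, v: np.ndarray) -> OnsetFit:
    """Error-function fit of a velocity time course to locate flow onset.

    Fits v(t) = base + amplitude * erf((t - t0) / width); t0 defines the
    reference time point of the recording.  Raises for fewer than 8 points
    or a degenerate (flat) time course.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if t.size < 8:
        raise InvalidParameterError("need >= 8 time points spanning the rise")
    if np.ptp(v) < 1e-12 or np.std(v) < 1e-12:
        raise DegenerateInputError("constant velocity: no rise to fit")

    def model(tt, base, amp, t0, width):
        return base + amp * erf((tt - t0) / width)

    vs = gaussian_filter1d(v, 1.0, mode="nearest")
    t0_guess = t[int(np.argmax(np.abs(np.gradient(vs, t))))]
    p0 = [float(v.mean()), float((v[-1] - v[0]) / 2), float(t0_guess),
          float(np.ptp(t) / 5)]
    try:
        popt, pcov = curve_fit(model, t, v, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"onset fit did not converge: {exc}") from exc
    resid = v - model(t, *popt)
    return OnsetFit(
        t0=float(popt[2]),
        width=float(abs(popt[3])),
        base=float(popt[0]),
        amplitude=float(popt[1]),
        cov=pcov,
        rss=float(resid @ resid),
    )


def detect_stationary_window(
    t: np.ndarray,
    series: list[np.ndarray] | np.ndarray,
    rel_tol: float = 0.1,
    min_duration: float = 1.0,
) -> StationaryWindow:
    """Longest contiguous window in which every series is stationary.

    A window qualifies when each series stays within ``rel_tol`` of its own
    window median (tolerance floored at ``rel_tol`` times a tenth of the
    series range, so near-zero plateaus are not penalised) and lasts at
    least ``min_duration`` minutes.  Raises when no window qualifies.
    """
    t = np.asarray(t, float)
    if isinstance(series, np.ndarray) and series.ndim == 1:
        series = [series]
    series = [np.asarray(s, float) for s in series]
    for s in series:
        if s.shape != t.shape:
            raise InvalidParameterError("series must share the time grid")
    n = t.size
    best: StationaryWindow | None = None
    for i in range(n):
        for j in range(n - 1, i, -1):
            if t[j] - t[i] < min_duration:
                break
            if best is not None and t[j] - t[i] <= best.t_end - best.t_start:
                break
            ok = True
            for s in series:
                win = s[i : j + 1]
                med = np.median(win)
                tol = rel_tol * max(abs(med), 0.1 * np.ptp(s))
                if np.max(np.abs(win - med)) > tol:
                    ok = False
                    break
            if ok:
                best = StationaryWindow(float(t[i]), float(t[j]), i, j)
                break
    if best is None:
        raise DegenerateInputError("no stationary window found")
    return best


def intensity_profile(
    image: np.ndarray,
    y_band: tuple[int, int] | None = None,
    pixel_size: float = 1.0,
    subtract_edge_background: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-mean AP intensity profile (x_um, intensity) of one channel.

    ``y_band`` is a (row_lo, row_hi) pixel range (inclusive-exclusive);
    optionally subtracts the median of the top and bottom image rows as a
    background estimate.  Two channels processed with identical arguments
    share identical grids by construction.
    """
    image = np.asarray(image, float)
    h, w = image.shape
    if y_band is None:
        band = image
    else:
        band = image[y_band[0] : y_band[1]]
        if band.size == 0:
            raise DegenerateInputError("empty y band")
    prof = band.mean(axis=0)
    if subtract_edge_background:
        prof = prof - float(np.median(np.concatenate([image[0], image[-1]])))
    x_um = (np.arange(w) - (w - 1) / 2) * pixel_size
    return x_um, prof
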