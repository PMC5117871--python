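"""Nematic order quantification of filament images via windowed Fourier spectra.

The power spectrum of a small image window concentrates perpendicular to the
dominant real-space filament orientation.  Binning the spectral power within
a wavenumber annulus by angle (rotated by pi/2 back to real space) gives an
angular distribution p(theta) on [0, pi), from which the 2-D nematic order
tensor follows as its second circular moments:

    Qxx = int p(theta) cos 2theta dtheta,   Qxy = int p(theta) sin 2theta dtheta.

Angles are measured from the AP (x) axis; theta = pi/2 is circumferential
("vertical").  The scalar order parameter used throughout is Q = -Qxx, so
that circumferential alignment is positive.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.exposure import equalize_hist

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "OrientationField",
    "NematicProfile",
    "window_orientation_spectrum",
    "nematic_tensor_from_spectrum",
    "compute_nematic_field",
    "nematic_profile",
]

N_ANGLE_BINS = 180  # 1 degree bins on [0, pi)

#: Spectral annulus in spatial periods (px): select filament-width scales,
#: exclude DC/illumination gradients and near-Nyquist noise.
PERIOD_RANGE = (4.0, 16.0)


@dataclasses.dataclass
class OrientationField:
    """Per-window nematic tensor field on a regular grid of window centres."""

    x_px: np.ndarray  # 1-D, window-centre columns
    y_px: np.ndarray  # 1-D, window-centre rows
    Qxx: np.ndarray  # 2-D (len(y), len(x))
    Qxy: np.ndarray
    pixel_size: float = 1.0
    window_px: int = 32

    @property
    def theta(self) -> np.ndarray:
        """Dominant filament angle in [0, pi), from the AP axis."""
        return 0.5 * np.arctan2(self.Qxy, self.Qxx) % np.pi

    @property
    def A(self) -> np.ndarray:
        """Nematic magnitude sqrt(Qxx^2 + Qxy^2), in [0, 1]."""
        return np.hypot(self.Qxx, self.Qxy)

    @property
    def x_um(self) -> np.ndarray:
        return (self.x_px - np.mean(self.x_px)) * self.pixel_size

    @property
    def y_um(self) -> np.ndarray:
        return (self.y_px - np.mean(self.y_px)) * self.pixel_size

    def mean_Q(self) -> float:
        """Spatial mean of the scalar order parameter Q = -Qxx."""
        return float(np.mean(-self.Qxx))


@dataclasses.dataclass
class NematicProfile:
    """Scalar nematic order Q(x) = -<Qxx> along the AP axis."""

    x: np.ndarray  # um
    Q: np.ndarray
    Qxy: np.ndarray | None = None


def window_orientation_spectrum(
    window: np.ndarray,
    n_bins: int = N_ANGLE_BINS,
    period_range: tuple[float, float] = PERIOD_RANGE,
    background_subtract: bool = True,
) -> np.ndarray:
    """Angular distribution p(theta) of filament orientation in one window.

    The window is mean-subtracted, Hann-tapered and Fourier transformed; the
    spectral power inside the wavenumber annulus ``period_range`` is binned
    by angle after removing the radially averaged (isotropic) floor, then
    rotated by pi/2 so that theta refers to real-space filament orientation.
    Returns p over ``n_bins`` bins on [0, pi) normalised so that
    sum(p) * (pi / n_bins) = 1.  A constant window has no defined
    orientation and yields the flat distribution.
    """
    win = np.asarray(window, float)
    if win.ndim != 2 or min(win.shape) < 16:
        raise InvalidParameterError("window must be 2-D and at least 16 px")
    flat = np.full(n_bins, 1.0 / np.pi)
    if np.ptp(win) == 0:
        return flat

    h, w = win.shape
    taper = np.outer(np.hanning(h), np.hanning(w))
    F = np.fft.fft2((win - win.mean()) * taper)
    P = np.abs(F) ** 2

    fy = np.fft.fftfreq(h)[:, None]  # cycles per px along rows
    fx = np.fft.fftfreq(w)[None, :]
    rho = np.hypot(fx, fy)
    lo, hi = 1.0 / period_range[1], 1.0 / period_range[0]
    annulus = (rho >= lo) & (rho <= hi)

    power = P[annulus]
    if background_subtract:
        # remove the isotropic noise floor: per radial shell, subtract the
        # angular mean of the power, clipping at zero
        k = np.rint(rho[annulus] * min(h, w)).astype(int)
        sums = np.bincount(k, weights=power)
        counts = np.bincount(k)
        radial_mean = np.zeros_like(sums)
        nz = counts > 0
        radial_mean[nz] = sums[nz] / counts[nz]
        power = np.clip(power - radial_mean[k], 0.0, None)

    # rows grow downward, so the upward y frequency is -fy; rotate by pi/2
    # to convert the spectral normal into the filament orientation
    theta = (np.arctan2(-fy + np.zeros_like(fx), fx + np.zeros_like(fy)) + np.pi / 2) % np.pi
    bins = np.minimum((theta[annulus] / np.pi * n_bins).astype(int), n_bins - 1)
    p = np.bincount(bins, weights=power, minlength=n_bins)
    total = p.sum()
    if total <= 0:
        return flat
    return p / total / (np.pi / n_bins)


def nematic_tensor_from_spectrum(p: np.ndarray) -> tuple[float, float]:
    """Second circular moments (Qxx, Qxy) of a normalised angular distribution."""
    p = np.asarray(p, float)
    n = p.size
    dtheta = np.pi / n
    if not np.isclose(p.sum() * dtheta, 1.0, atol=1e-6):
        raise InvalidParameterError("p must be normalised to integrate to 1")
    theta = (np.arange(n) + 0.5) * dtheta
    qxx = float(np.sum(p * np.cos(2 * theta)) * dtheta)
    qxy = float(np.sum(p * np.sin(2 * theta)) * dtheta)
    return qxx, qxy


def compute_nematic_field(
    image: np.ndarray,
    window_px: int = 32,
    stride_px: int = 16,
    cdf_equalize: bool = True,
    pixel_size: float = 1.0,
) -> OrientationField:
    """Windowed nematic tensor field of a filament image.

    Windows of ``window_px`` on a ``stride_px`` grid are (optionally) passed
    through per-window histogram equalisation — the empirical-CDF intensity
    map, which makes the result invariant to intensity rescaling — and each
    window's orientation spectrum is reduced to (Qxx, Qxy).
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise InvalidParameterError("image must be 2-D")
    h, w = image.shape
    if h < window_px or w < window_px:
        raise InvalidParameterError("image smaller than the analysis window")

    rows = np.arange(0, h - window_px + 1, stride_px)
    cols = np.arange(0, w - window_px + 1, stride_px)
    Qxx = np.empty((rows.size, cols.size))
    Qxy = np.empty_like(Qxx)
    for i, r in enumerate(rows):
        for j, col in enumerate(cols):
            win = image[r : r + window_px, col : col + window_px]
            if cdf_equalize and np.ptp(win) > 0:
                win = equalize_hist(win)
            p = window_orientation_spectrum(win)
            Qxx[i, j], Qxy[i, j] = nematic_tensor_from_spectrum(p)
    return OrientationField(
        x_px=cols + window_px / 2,
        y_px=rows + window_px / 2,
        Qxx=Qxx,
        Qxy=Qxy,
        pixel_size=pixel_size,
        window_px=window_px,
    )


def nematic_profile(
    field: OrientationField,
    y_band: tuple[float, float] | None = None,
) -> NematicProfile:
    """Reduce an orientation field to Q(x) = -<Qxx> over a horizontal band.

    ``y_band`` is a (low, high) range in the field's micrometre y coordinate;
    None averages over all rows.  Raises when the band selects no rows.
    """
    if y_band is None:
        mask = np.ones(field.y_px.size, bool)
    else:
        y = field.y_um
        mask = (y >= y_band[0]) & (y <= y_band[1])
    if not np.any(mask):
        raise DegenerateInputError("empty y band")
    return NematicProfile(
        x=field.x_um,
        Q=-np.mean(field.Qxx[mask], axis=0),
        Qxy=np.mean(field.Qxy[mask], axis=0),
    )
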