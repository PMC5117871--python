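"""Synthetic data with known ground truth.

Three generators stand in for the raw microscopy of the study system (the
*C. elegans* zygote cortex):

* filament-network images — randomly grown filaments with a controllable
  orientation bias B toward vertical (circumferential), rendered through a
  Gaussian PSF at a requested signal-to-noise ratio;
* flow profiles — analytic v(x) shapes (Gaussian bump, tanh front, linear)
  with exact derivatives, and image advection under such flows;
* embryo profile sets — steady-state nematic order generated by the gel
  forward model plus Gaussian measurement noise, bundled with the flow,
  compression and myosin fields and the generating parameters.

All stochastic operations take an explicit integer seed; there is no global
random state, and identical seeds give bit-identical output.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import interp1d
from scipy.ndimage import gaussian_filter, map_coordinates

from .datasets import EmbryoDataset
from .errors import InvalidParameterError
from .gel import GelParameters, solve_steady_Q

__all__ = [
    "MeshworkParams",
    "FlowProfileSpec",
    "MyosinBandSpec",
    "FlowField",
    "sample_start_angles",
    "generate_filament_image",
    "generate_flow_profile",
    "advect_image",
    "generate_embryo_dataset",
]


@dataclasses.dataclass
class MeshworkParams:
    """Parameters of the artificial filamentous network.

    n_filaments       filaments per image (the study varies 60-120)
    bias_B            strength of the vertical bias of the *starting*
                      direction; B = 0 gives a uniform angle distribution
    filament_length   mean filament length, px
    step_length       growth step, px
    angular_diffusion per-step direction wander (sd of the Gaussian
                      increment), rad
    image_size        (height, width), px
    pixel_size        um per px
    psf_sigma         Gaussian PSF sigma, px
    snr               (peak filament intensity - background mean) /
                      background sd; must be > 0
    seed              integer seed; identical seed + params give
                      bit-identical images
    """

    n_filaments: int = 90
    bias_B: float = 0.0
    filament_length: float = 40.0
    step_length: float = 2.0
    angular_diffusion: float = 0.15
    image_size: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1
    psf_sigma: float = 1.5
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_filaments < 1:
            raise InvalidParameterError("n_filaments must be >= 1")
        if self.bias_B < 0:
            raise InvalidParameterError("bias_B must be >= 0")
        if self.snr <= 0:
            raise InvalidParameterError("snr must be > 0")
        if min(self.image_size) < 8:
            raise InvalidParameterError("image_size too small")
        if self.filament_length <= 0 or self.step_length <= 0:
            raise InvalidParameterError("lengths must be > 0")


def sample_start_angles(n: int, bias_B: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n starting orientations from the wrapped nematic distribution
    p(theta) proportional to exp(B cos 2(theta - pi/2)) on [0, pi).

    Uniform at B = 0; increasingly concentrated toward vertical (pi/2) as B
    grows.  Sampled by rejection with envelope exp(B)."""
    if bias_B == 0:
        return rng.uniform(0.0, np.pi, n)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = 2 * (n - filled) + 8
        theta = rng.uniform(0.0, np.pi, m)
        accept = rng.uniform(0.0, 1.0, m) < np.exp(
            bias_B * (np.cos(2 * (theta - np.pi / 2)) - 1.0)
        )
        good = theta[accept]
        take = min(good.size, n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def generate_filament_image(params: MeshworkParams) -> np.ndarray:
    """Render one synthetic filament-network image (float array, H x W).

    Filaments are seeded at uniform random positions; only the *initial*
    growth direction is biased toward vertical (concentration set by
    ``bias_B``), after which the direction performs a Gaussian random walk
    with per-step sd ``angular_diffusion``.  Filament intensity is deposited
    as dense sub-pixel points, blurred by the Gaussian PSF and overlaid on a
    noisy background scaled to the requested SNR.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.image_size
    acc = np.zeros((h, w))

    thetas = sample_start_angles(p.n_filaments, p.bias_B, rng)
    # nematic orientation -> random polarity of growth
    thetas = thetas + np.pi * rng.integers(0, 2, p.n_filaments)
    ys = rng.uniform(0, h, p.n_filaments)
    xs = rng.uniform(0, w, p.n_filaments)
    # length spread around the mean (gamma, shape 4) keeps lengths positive
    lengths = rng.gamma(4.0, p.filament_length / 4.0, p.n_filaments)

    sub = 0.5  # deposition spacing, px
    for i in range(p.n_filaments):
        n_steps = max(1, int(round(lengths[i] / p.step_length)))
        theta = thetas[i]
        y, x = ys[i], xs[i]
        for _ in range(n_steps):
            ny = y - p.step_length * np.sin(theta)  # rows grow downward
            nx = x + p.step_length * np.cos(theta)
            n_sub = max(1, int(np.ceil(p.step_length / sub)))
            t = (np.arange(n_sub) + 0.5) / n_sub
            py = np.rint(y + (ny - y) * t).astype(int)
            px = np.rint(x + (nx - x) * t).astype(int)
            inside = (py >= 0) & (py < h) & (px >= 0) & (px < w)
            np.add.at(acc, (py[inside], px[inside]), 1.0)
            y, x = ny, nx
            theta += rng.normal(0.0, p.angular_diffusion)

    signal = gaussian_filter(acc, p.psf_sigma)
    peak = signal.max()
    if peak > 0:
        signal = signal * (p.snr / peak)
    background = 10.0 + rng.normal(0.0, 1.0, (h, w))
    return background + signal


@dataclasses.dataclass
class FlowProfileSpec:
    """Analytic AP flow profile.

    shape          'gaussian_bump', 'tanh_front' or 'linear'
    peak_velocity  um/min; for 'linear' the slope is peak_velocity / width
    center         um
    width          um, > 0
    grid           sampled x positions, um, strictly increasing
    """

    shape: str
    peak_velocity: float
    width: float
    grid: np.ndarray
    center: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian_bump", "tanh_front", "linear"):
            raise InvalidParameterError(f"unknown shape {self.shape!r}")
        if self.width <= 0:
            raise InvalidParameterError("width must be > 0")
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise InvalidParameterError("grid must be strictly increasing")


@dataclasses.dataclass
class FlowField:
    """Velocity profile with its analytic spatial derivative."""

    x: np.ndarray
    v: np.ndarray
    dvdx: np.ndarray

    def v_at(self, x) -> np.ndarray:
        return interp1d(
            self.x, self.v, kind="cubic", bounds_error=False,
            fill_value=(self.v[0], self.v[-1]),
        )(x)


def generate_flow_profile(spec: FlowProfileSpec) -> FlowField:
    """Evaluate the analytic flow profile and its exact derivative on the grid."""
    x = spec.grid
    s = x - spec.center
    if spec.shape == "gaussian_bump":
        env = np.exp(-(s**2) / (2 * spec.width**2))
        v = spec.peak_velocity * env
        dvdx = spec.peak_velocity * (-s / spec.width**2) * env
    elif spec.shape == "tanh_front":
        v = 0.5 * spec.peak_velocity * (1 + np.tanh(s / spec.width))
        dvdx = 0.5 * spec.peak_velocity / spec.width / np.cosh(s / spec.width) ** 2
    else:  # linear
        slope = spec.peak_velocity / spec.width
        v = slope * s
        dvdx = np.full_like(x, slope)
    return FlowField(x=x, v=v, dvdx=dvdx)


def advect_image(
    image: np.ndarray,
    flow: FlowField,
    dt: float,
    pixel_size: float,
) -> np.ndarray:
    """Warp an image by the displacement field v(x) * dt along the AP axis.

    Image columns are mapped to physical coordinates with the embryo centre
    at the image centre.  The warp uses the inverse map (fixed-point iterated
    so that a pixel is pulled from the position that flows onto it) and cubic
    interpolation.  Raises when any displacement exceeds the image width.
    """
    image = np.asarray(image, float)
    h, w = image.shape
    x_um = (np.arange(w) - (w - 1) / 2) * pixel_size

    def disp_px(xq_um):
        return flow.v_at(xq_um) * dt / pixel_size

    if np.max(np.abs(disp_px(x_um))) >= w:
        raise InvalidParameterError("displacement exceeds image width")

    cols = np.arange(w, dtype=float)
    src = cols.copy()
    for _ in range(8):  # invert x_dest = x_src + d(x_src)
        src = cols - disp_px((src - (w - 1) / 2) * pixel_size)
    rows = np.arange(h, dtype=float)
    coords = np.meshgrid(rows, src, indexing="ij")
    return map_coordinates(image, coords, order=3, mode="nearest")


@dataclasses.dataclass
class MyosinBandSpec:
    """Gaussian myosin band: c(x) = baseline + amplitude * gaussian(center, width)."""

    baseline: float = 1.0
    amplitude: float = 1.0
    center: float = 0.0
    width: float = 4.0

    def evaluate(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        return self.baseline + self.amplitude * np.exp(
            -((x - self.center) ** 2) / (2 * self.width**2)
        )


def generate_embryo_dataset(
    gel: GelParameters,
    flow: FlowProfileSpec,
    myosin: MyosinBandSpec | None = None,
    noise_sigma_Q: float = 0.0,
    n_embryos: int = 1,
    seed: int = 0,
) -> list[EmbryoDataset]:
    """Generate synthetic embryo profile sets with known ground truth.

    The noiseless nematic profile comes from the steady-state forward model
    (:func:`nemacortex.gel.solve_steady_Q`) driven by the analytic flow; each
    embryo adds i.i.d. Gaussian noise of sd ``noise_sigma_Q`` to Q.  The
    generating :class:`GelParameters` are stored as ``truth``.
    """
    if noise_sigma_Q < 0:
        raise InvalidParameterError("noise_sigma_Q must be >= 0")
    if n_embryos < 1:
        raise InvalidParameterError("n_embryos must be >= 1")
    field = generate_flow_profile(flow)
    c = myosin.evaluate(field.x) if myosin is not None else None
    Q0 = solve_steady_Q(field.x, field.v, field.dvdx, gel, c=c)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_embryos):
        noise = (
            rng.normal(0.0, noise_sigma_Q, Q0.shape) if noise_sigma_Q > 0 else 0.0
        )
        out.append(
            EmbryoDataset(
                x=field.x.copy(),
                v=field.v.copy(),
                dvdx=field.dvdx.copy(),
                Q=Q0 + noise,
                c=None if c is None else c.copy(),
                noise_sigma_Q=noise_sigma_Q,
                truth=gel,
            )
        )
    return out
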