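"""One-dimensional active nematic gel: solvers, fitting, identifiability.

The cortical actomyosin layer is treated as a thin film of an active
nematic gel flowing along the AP axis.  The scalar nematic order Q(x, t)
(Q > 0: filaments aligned circumferentially, i.e. orthogonal to the flow)
obeys

    dQ/dt = -v dQ/dx - (beta/2) dv/dx - Q/tau + (ell^2/tau) d2Q/dx2
            [+ (lambda' c/c0) Q / tau]

where v(x) is the cortical flow velocity, tau the relaxation time of
order, beta the flow-alignment coupling, ell the alignment length and the
optional last term a myosin-concentration-weighted active alignment.
During the stationary flow phase (dQ/dt = 0) this reduces, after
multiplying by tau, to the linear two-point boundary-value problem

    ell^2 Q'' - tau v Q' - (1 - lambda'tau c/c0) Q = (beta tau / 2) v' ,

with Dirichlet boundary values C1, C2 at the fit-domain edges.  Only the
products beta*tau and lambda'*tau are identifiable from the steady state,
which is why the parameters are stored as such.

Fitting minimises the sum of squared differences between the solved and
measured Q profiles over (tau, beta*tau, ell[, lambda'tau], C1, C2).
Because the steady solution is linear in beta*tau and affine in (C1, C2),
those three are profiled out exactly by linear least squares at every step
of the nonlinear search, which only runs over (tau, ell[, lambda'tau]).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import solve_banded
from scipy.optimize import least_squares

from .datasets import EmbryoDataset, average_datasets
from .errors import FitError, InstabilityError, InvalidParameterError

__all__ = [
    "GelParameters",
    "FitResult",
    "BootstrapResult",
    "ScanResult",
    "solve_steady_Q",
    "simulate_Q_dynamics",
    "fit_gel_parameters",
    "bootstrap_parameters",
    "identifiability_scan",
    "decompose_alignment_terms",
]

#: Default fit region, micrometres: the 30 um central region of the embryo.
DEFAULT_FIT_REGION = (-15.0, 15.0)

#: Grid refinement target for the finite-difference solver (um); ell values
#: down to ~1.7 um must be resolved by several points.
DEFAULT_MAX_DX = 0.25

#: Upper bound below which tau is declared undeterminable ("< 0.5 (n.d.)").
TAU_DETECTION_BOUND = 0.5

#: Flat-region tolerance: residual changes smaller than this fraction of the
#: total sum of squares of Q are considered insignificant.
FLAT_TOL = 0.01


@dataclasses.dataclass
class GelParameters:
    """Material parameters of the active nematic gel.

    tau        relaxation time of nematic order, minutes (>= 0)
    beta_tau   product beta*tau, minutes (flow-alignment coupling)
    ell        alignment length, micrometres (> 0)
    lambda_tau product lambda'*tau, dimensionless (>= 0); myosin-coupled
               active alignment, lambda = lambda' * c/c0
    C1, C2     boundary values of Q at the left/right fit-domain edges
    """

    tau: float
    beta_tau: float
    ell: float
    lambda_tau: float = 0.0
    C1: float = 0.0
    C2: float = 0.0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise InvalidParameterError("tau must be >= 0")
        if self.ell <= 0:
            raise InvalidParameterError("ell must be > 0")
        if self.lambda_tau < 0:
            raise InvalidParameterError("lambda_tau must be >= 0")

    @property
    def beta(self) -> float:
        """Dimensionless flow-alignment coefficient beta = beta_tau / tau."""
        if self.tau <= 0:
            raise InvalidParameterError("beta undefined for tau = 0")
        return self.beta_tau / self.tau


@dataclasses.dataclass
class FitResult:
    params: GelParameters
    rss: float
    tss: float
    ci95: dict
    tau_unbounded_below: bool
    n_points: int

    @property
    def tau_report(self) -> str:
        """Table-style tau entry: '< 0.5 (n.d.)' when only a bound is known."""
        if self.tau_unbounded_below:
            return f"< {TAU_DETECTION_BOUND} (n.d.)"
        return f"{self.params.tau:.3g}"

    @property
    def tau_bound(self) -> float:
        """Reported tau: the detection bound when tau is unidentifiable."""
        if self.tau_unbounded_below:
            return TAU_DETECTION_BOUND
        return self.params.tau


@dataclasses.dataclass
class BootstrapResult:
    median: dict
    interval: dict  # parameter -> (16th, 84th) percentile
    samples: dict
    n_boot: int
    seed: int
    low_n_boot_warning: bool


@dataclasses.dataclass
class ScanResult:
    param_name: str
    values: np.ndarray
    rss: np.ndarray
    tss: float
    flat_bound: float | None

    @property
    def normalized_rss(self) -> np.ndarray:
        return (self.rss - self.rss.min()) / self.tss


# ----------------------------------------------------------------------
# forward solvers


def _check_grid(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if x.ndim != 1 or x.size < 5:
        raise InvalidParameterError("need a 1-D grid with >= 5 points")
    dx = np.diff(x)
    if np.any(dx <= 0):
        raise InvalidParameterError("grid must be strictly increasing")
    if not np.allclose(dx, dx[0], rtol=1e-6):
        raise InvalidParameterError("grid must be uniform")
    return float(dx[0])


def _relaxation_coeff(lambda_tau: float, c: np.ndarray | None) -> np.ndarray | float:
    """Coefficient a(x) = 1 - lambda'tau * c/c0; the lambda term is off when
    no myosin profile is supplied."""
    if c is None or lambda_tau == 0.0:
        return 1.0
    c = np.asarray(c, float)
    c0 = float(np.mean(c))
    if c0 <= 0:
        raise InvalidParameterError("myosin concentration must have positive mean")
    a = 1.0 - lambda_tau * c / c0
    if np.any(a <= 0):
        raise InstabilityError(
            "active alignment too strong: 1 - lambda'tau c/c0 <= 0 on the domain"
        )
    return a


def _steady_solve_multi(
    x: np.ndarray,
    v: np.ndarray,
    tau: float,
    ell: float,
    a,
    rhs_list: list[np.ndarray],
    bc_list: list[tuple[float, float]],
) -> np.ndarray:
    """Solve ell^2 Q'' - tau v Q' - a Q = rhs for several (rhs, bc) pairs.

    Centered second-order finite differences; one banded factorisation serves
    all right-hand sides.  Returns an array of shape (len(rhs_list), n).
    """
    n = x.size
    dx = float(x[1] - x[0])
    a_arr = np.broadcast_to(np.asarray(a, float), (n,))
    diff = ell**2 / dx**2
    adv = tau * v / (2 * dx)

    ab = np.zeros((3, n))
    # interior rows i = 1..n-2
    ab[0, 2:] = diff - adv[1:-1]          # superdiagonal -> Q_{i+1}
    ab[1, 1:-1] = -2 * diff - a_arr[1:-1]  # diagonal
    ab[2, :-2] = diff + adv[1:-1]          # subdiagonal -> Q_{i-1}
    # Dirichlet boundary rows
    ab[1, 0] = 1.0
    ab[1, -1] = 1.0
    ab[0, 1] = 0.0
    ab[2, -2] = 0.0

    b = np.empty((n, len(rhs_list)))
    for k, (rhs, (c1, c2)) in enumerate(zip(rhs_list, bc_list)):
        b[:, k] = rhs
        b[0, k] = c1
        b[-1, k] = c2
    try:
        sol = solve_banded((1, 1), ab, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise FitError(f"singular discretization: {exc}") from exc
    return sol.T


def _refined(x: np.ndarray, max_dx: float):
    """Return (x_fine, restrict) where restrict maps a fine-grid solution back
    onto x by cubic interpolation; identity when no refinement is needed."""
    dx = _check_grid(x)
    if dx <= max_dx + 1e-12:
        return x, None
    factor = int(np.ceil(dx / max_dx))
    n_fine = (x.size - 1) * factor + 1
    xf = np.linspace(x[0], x[-1], n_fine)
    return xf, lambda qf: CubicSpline(xf, qf)(x)


def solve_steady_Q(
    x,
    v,
    dvdx,
    params: GelParameters,
    c=None,
    max_dx: float = DEFAULT_MAX_DX,
) -> np.ndarray:
    """Solve the steady-state nematic order profile on the grid ``x``.

    Solves ell^2 Q'' - tau v Q' - (1 - lambda'tau c/c0) Q = (beta_tau/2) dvdx
    with Dirichlet values params.C1 at x[0] and params.C2 at x[-1].  The grid
    is refined internally to a spacing <= ``max_dx`` and the solution sampled
    back by cubic interpolation.  When ``c`` is None the active-alignment term
    is off regardless of ``params.lambda_tau``.
    """
    x = np.asarray(x, float)
    v = np.asarray(v, float)
    dvdx = np.asarray(dvdx, float)
    xf, restrict = _refined(x, max_dx)
    if restrict is not None:
        vf = np.interp(xf, x, v)
        dvf = np.interp(xf, x, dvdx)
        cf = np.interp(xf, x, c) if c is not None else None
    else:
        vf, dvf, cf = v, dvdx, c
    a = _relaxation_coeff(params.lambda_tau, cf)
    rhs = 0.5 * params.beta_tau * dvf
    (qf,) = _steady_solve_multi(
        xf, vf, params.tau, params.ell, a, [rhs], [(params.C1, params.C2)]
    )
    return restrict(qf) if restrict is not None else qf


def _steady_basis(x, v, dvdx, c, tau, ell, lambda_tau):
    """Basis profiles on the (already fine enough) grid x:

    Qb solves the BVP with beta_tau = 1 and zero boundaries, H1/H2 the
    homogeneous problem with unit boundary value on one side.  The full
    solution is ``beta_tau*Qb + C1*H1 + C2*H2`` — linear in all three.
    """
    a = _relaxation_coeff(lambda_tau, c)
    zeros = np.zeros_like(x)
    return _steady_solve_multi(
        x,
        v,
        tau,
        ell,
        a,
        [0.5 * np.asarray(dvdx, float), zeros, zeros],
        [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)],
    )


def simulate_Q_dynamics(
    x,
    v,
    dvdx,
    params: GelParameters,
    Q0,
    dt: float,
    t_end: float,
    c=None,
    store_every: int = 1,
):
    """Time-step the dynamic equation for Q under a static flow field.

    Backward-Euler step with advection, diffusion and relaxation all in the
    implicit (banded) operator, using the same centred stencils as the
    steady solver so that the long-time limit coincides with
    :func:`solve_steady_Q` on the same grid; the compression source is
    applied explicitly.  Dirichlet boundaries at C1/C2.  Requires tau > 0
    and a CFL-respecting dt (dt * max|v| <= dx), which also keeps the
    advection accurate in time.

    Returns ``(times, Qs)`` with Qs of shape (n_stored, n_x).
    """
    x = np.asarray(x, float)
    v = np.asarray(v, float)
    dvdx = np.asarray(dvdx, float)
    Q = np.asarray(Q0, float).copy()
    dx = _check_grid(x)
    if params.tau <= 0:
        raise InvalidParameterError("dynamics require tau > 0")
    if dt <= 0 or t_end <= 0:
        raise InvalidParameterError("dt and t_end must be > 0")
    vmax = float(np.max(np.abs(v)))
    if vmax * dt > dx * (1 + 1e-9):
        raise InvalidParameterError(
            f"CFL violation: dt*max|v| = {vmax * dt:.3g} exceeds dx = {dx:.3g}"
        )
    a = np.broadcast_to(
        np.asarray(_relaxation_coeff(params.lambda_tau, c), float), x.shape
    )
    n = x.size
    beta = params.beta_tau / params.tau
    diff = params.ell**2 / params.tau / dx**2

    # implicit operator M = I + dt*(a/tau + v*D1 - diff*D2) on interior rows
    adv = v / (2 * dx)
    ab = np.zeros((3, n))
    ab[0, 2:] = dt * (adv[1:-1] - diff)
    ab[1, 1:-1] = 1.0 + dt * a[1:-1] / params.tau + 2 * dt * diff
    ab[2, :-2] = dt * (-adv[1:-1] - diff)
    ab[1, 0] = 1.0
    ab[1, -1] = 1.0

    n_steps = int(np.ceil(t_end / dt))
    times = [0.0]
    stored = [Q.copy()]
    src = -0.5 * beta * dvdx
    for step in range(1, n_steps + 1):
        rhs = Q + dt * src
        rhs[0] = params.C1
        rhs[-1] = params.C2
        Q = solve_banded((1, 1), ab, rhs)
        if step % store_every == 0 or step == n_steps:
            times.append(step * dt)
            stored.append(Q.copy())
    return np.asarray(times), np.asarray(stored)


# ----------------------------------------------------------------------
# fitting


def _extract_profiles(data, fit_region, need_c):
    if isinstance(data, EmbryoDataset):
        x, v, dvdx, Q, c = data.x, data.v, data.dvdx, data.Q, data.c
    else:
        x, v, dvdx, Q = (np.asarray(a, float) for a in data[:4])
        c = np.asarray(data[4], float) if len(data) > 4 and data[4] is not None else None
    mask = (x >= fit_region[0]) & (x <= fit_region[1])
    if mask.sum() < 7:
        raise FitError("fewer grid points in the fit region than parameters")
    x, v, dvdx, Q = x[mask], v[mask], dvdx[mask], Q[mask]
    c = c[mask] if c is not None else None
    if need_c and c is None:
        raise InvalidParameterError("include_lambda requires a myosin profile c")
    return x, v, dvdx, Q, c


def _profiled_fit(x, v, dvdx, Q, c, tau, ell, lambda_tau):
    """Exact linear least squares for (beta_tau, C1, C2) at fixed nonlinear
    parameters; returns (residual vector, coefficients)."""
    basis = _steady_basis(x, v, dvdx, c, tau, ell, lambda_tau)
    M = basis.T  # columns: Qb, H1, H2
    coef, *_ = np.linalg.lstsq(M, Q, rcond=None)
    resid = Q - M @ coef
    return resid, coef


def fit_gel_parameters(
    data,
    include_lambda: bool = False,
    fit_region=DEFAULT_FIT_REGION,
    n_starts: int = 16,
    max_dx: float = DEFAULT_MAX_DX,
    flat_tol: float = FLAT_TOL,
) -> FitResult:
    """Fit (tau, beta_tau, ell[, lambda_tau], C1, C2) to a measured Q profile.

    ``data`` is an :class:`EmbryoDataset` or a tuple ``(x, v, dvdx, Q[, c])``
    on a common grid.  beta_tau, C1 and C2 are profiled out exactly by linear
    least squares; the nonlinear search runs over log tau, log ell and, when
    ``include_lambda``, lambda'tau, multi-started from a log-spaced grid.
    Ties in the residual are broken toward smaller tau.

    When refits with tau fixed anywhere in (0, 0.5] min change the residual
    by less than ``flat_tol`` of the total sum of squares, tau is reported as
    an upper bound only (``tau_unbounded_below``), mirroring the "< 0.5
    (n.d.)" table convention.
    """
    x, v, dvdx, Q, c = _extract_profiles(data, fit_region, include_lambda)
    xf, restrict = _refined(x, max_dx)
    if restrict is not None:
        # fit on the refined grid but score residuals on the data grid
        vf = np.interp(xf, x, v)
        dvf = np.interp(xf, x, dvdx)
        cf = np.interp(xf, x, c) if c is not None else None
    else:
        vf, dvf, cf = v, dvdx, c

    tss = float(np.sum((Q - Q.mean()) ** 2))
    if tss < 1e-20 and float(np.max(np.abs(dvdx))) < 1e-12:
        raise FitError("degenerate fit: flat Q and zero compression")

    if cf is not None:
        lam_max = 0.99 * float(np.mean(cf) / np.max(cf))
    else:
        lam_max = 0.0

    data_idx = (
        None
        if restrict is None
        else np.rint((x - xf[0]) / (xf[1] - xf[0])).astype(int)
    )

    def residuals(theta):
        tau, ell = np.exp(theta[0]), np.exp(theta[1])
        lam = theta[2] if include_lambda else 0.0
        try:
            basis = _steady_basis(xf, vf, dvf, cf, tau, ell, lam)
        except InstabilityError:
            return 1e3 * np.ones_like(Q)
        M = basis.T if data_idx is None else basis.T[data_idx]
        coef, *_ = np.linalg.lstsq(M, Q, rcond=None)
        return Q - M @ coef

    def solve_linear(tau, ell, lam):
        basis = _steady_basis(xf, vf, dvf, cf, tau, ell, lam)
        M = basis.T if data_idx is None else basis.T[data_idx]
        coef, *_ = np.linalg.lstsq(M, Q, rcond=None)
        resid = Q - M @ coef
        return float(resid @ resid), coef

    # multi-start over a log grid in (tau, ell); lambda starts near zero
    side = max(2, int(round(np.sqrt(n_starts))))
    tau_starts = np.geomspace(0.05, 10.0, side)
    ell_starts = np.geomspace(0.5, 10.0, side)
    lo = [-np.inf, -np.inf]
    hi = [np.inf, np.inf]
    if include_lambda:
        lo.append(0.0)
        hi.append(lam_max)

    best = None
    for t0 in tau_starts:
        for l0 in ell_starts:
            x0 = [np.log(t0), np.log(l0)]
            if include_lambda:
                x0.append(min(0.1, 0.5 * lam_max))
            try:
                sol = least_squares(
                    residuals,
                    x0,
                    bounds=(lo, hi),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                    max_nfev=300,
                )
            except Exception:
                continue
            rss = float(sol.fun @ sol.fun)
            tau_here = float(np.exp(sol.x[0]))
            if (
                best is None
                or rss < best[0] * (1 - 1e-9)
                or (rss <= best[0] * (1 + 1e-9) and tau_here < best[1])
            ):
                best = (rss, tau_here, sol)
    if best is None:
        raise FitError("all optimizer starts failed")
    rss, tau_hat, sol = best
    ell_hat = float(np.exp(sol.x[1]))
    lam_hat = float(sol.x[2]) if include_lambda else 0.0
    rss, coef = solve_linear(tau_hat, ell_hat, lam_hat)
    params = GelParameters(
        tau=tau_hat,
        beta_tau=float(coef[0]),
        ell=ell_hat,
        lambda_tau=lam_hat,
        C1=float(coef[1]),
        C2=float(coef[2]),
    )

    # tau flat-region rule on (0, 0.5]: refit the linear parameters with tau
    # fixed; insignificant residual change over the whole interval means only
    # the upper bound is identified.
    flat = True
    for tau_probe in np.geomspace(0.05, TAU_DETECTION_BOUND, 8):
        rss_probe, _ = solve_linear(tau_probe, ell_hat, lam_hat)
        if (rss_probe - rss) / tss > flat_tol:
            flat = False
            break

    ci95 = _linearized_ci(
        xf, vf, dvf, cf, Q, data_idx, params, include_lambda, rss
    )
    return FitResult(
        params=params,
        rss=rss,
        tss=tss,
        ci95=ci95,
        tau_unbounded_below=flat,
        n_points=Q.size,
    )


def _linearized_ci(xf, vf, dvf, cf, Q, data_idx, params, include_lambda, rss):
    """95% confidence intervals from the Jacobian at the optimum."""
    names = ["tau", "beta_tau", "ell", "C1", "C2"]
    if include_lambda:
        names.insert(3, "lambda_tau")

    def model(p):
        pars = dict(zip(names, p))
        gp = GelParameters(
            tau=pars["tau"],
            beta_tau=pars["beta_tau"],
            ell=pars["ell"],
            lambda_tau=pars.get("lambda_tau", 0.0),
            C1=pars["C1"],
            C2=pars["C2"],
        )
        a = _relaxation_coeff(gp.lambda_tau, cf)
        rhs = 0.5 * gp.beta_tau * dvf
        (qf,) = _steady_solve_multi(
            xf, vf, gp.tau, gp.ell, a, [rhs], [(gp.C1, gp.C2)]
        )
        return qf if data_idx is None else qf[data_idx]

    p0 = np.array(
        [getattr(params, n) for n in names]
    )
    n_pts, n_par = Q.size, p0.size
    J = np.empty((n_pts, n_par))
    f0 = model(p0)
    for j in range(n_par):
        h = 1e-6 * max(abs(p0[j]), 1e-3)
        p = p0.copy()
        p[j] += h
        try:
            J[:, j] = (model(p) - f0) / h
        except (InstabilityError, InvalidParameterError):
            p[j] -= 2 * h
            J[:, j] = (f0 - model(p)) / h
    dof = max(n_pts - n_par, 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.inf)
    return {
        name: (float(p0[j] - 1.96 * se[j]), float(p0[j] + 1.96 * se[j]))
        for j, name in enumerate(names)
    }


def bootstrap_parameters(
    datasets: list[EmbryoDataset],
    n_boot: int = 1000,
    seed: int = 0,
    include_lambda: bool = False,
    fit_region=DEFAULT_FIT_REGION,
    n_starts: int = 4,
) -> BootstrapResult:
    """Bootstrap over embryos: resample with replacement, average the
    co-registered profiles per resample, refit, and report the median with
    the 68% (16th-84th percentile) interval per parameter."""
    if len(datasets) < 2:
        raise InvalidParameterError("bootstrap needs >= 2 embryos")
    low_warning = n_boot < 100
    if low_warning:
        warnings.warn("n_boot < 100 gives unreliable intervals", stacklevel=2)
    rng = np.random.default_rng(seed)
    names = ["tau", "beta_tau", "ell", "lambda_tau", "C1", "C2"]
    samples = {n: [] for n in names}
    n_emb = len(datasets)
    for _ in range(n_boot):
        idx = rng.integers(0, n_emb, n_emb)
        avg = average_datasets([datasets[i] for i in idx])
        fit = fit_gel_parameters(
            avg,
            include_lambda=include_lambda,
            fit_region=fit_region,
            n_starts=n_starts,
        )
        for n in names:
            samples[n].append(getattr(fit.params, n))
    samples = {n: np.asarray(vals) for n, vals in samples.items()}
    median = {n: float(np.median(v)) for n, v in samples.items()}
    interval = {
        n: (float(np.percentile(v, 16)), float(np.percentile(v, 84)))
        for n, v in samples.items()
    }
    return BootstrapResult(
        median=median,
        interval=interval,
        samples=samples,
        n_boot=n_boot,
        seed=seed,
        low_n_boot_warning=low_warning,
    )


def identifiability_scan(
    data,
    param_name: str,
    grid,
    fixed_params: GelParameters,
    fit_region=DEFAULT_FIT_REGION,
    max_dx: float = DEFAULT_MAX_DX,
    flat_tol: float = FLAT_TOL,
) -> ScanResult:
    """Residual curve over one parameter with C1, C2-only refits.

    For each grid value the named parameter is set, all other material
    parameters stay at ``fixed_params``, and only the boundary values are
    re-fit (an exact 2-column linear least squares).  The flat region is the
    contiguous run from the low end of the grid whose residuals stay within
    ``flat_tol`` of the minimum, normalised by the total sum of squares; its
    upper edge is returned as ``flat_bound`` (None when the first grid point
    already lies outside it).
    """
    if param_name not in ("tau", "beta_tau", "ell", "lambda_tau"):
        raise InvalidParameterError(f"unknown parameter {param_name!r}")
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise InvalidParameterError("empty scan grid")
    need_c = param_name == "lambda_tau" or fixed_params.lambda_tau > 0
    x, v, dvdx, Q, c = _extract_profiles(data, fit_region, need_c)
    xf, restrict = _refined(x, max_dx)
    if restrict is not None:
        vf = np.interp(xf, x, v)
        dvf = np.interp(xf, x, dvdx)
        cf = np.interp(xf, x, c) if c is not None else None
        data_idx = np.rint((x - xf[0]) / (xf[1] - xf[0])).astype(int)
    else:
        vf, dvf, cf, data_idx = v, dvdx, c, None

    tss = float(np.sum((Q - Q.mean()) ** 2))
    rss = np.empty(grid.size)
    for i, value in enumerate(grid):
        pars = dataclasses.replace(fixed_params, **{param_name: float(value)})
        basis = _steady_basis(xf, vf, dvf, cf, pars.tau, pars.ell, pars.lambda_tau)
        full = basis.T if data_idx is None else basis.T[data_idx]
        target = Q - pars.beta_tau * full[:, 0]
        M = full[:, 1:]
        coef, *_ = np.linalg.lstsq(M, target, rcond=None)
        r = target - M @ coef
        rss[i] = float(r @ r)

    rel = (rss - rss.min()) / tss if tss > 0 else np.zeros_like(rss)
    flat_bound = None
    if rel[0] <= flat_tol:
        k = 0
        while k + 1 < grid.size and rel[k + 1] <= flat_tol:
            k += 1
        flat_bound = float(grid[k])
    return ScanResult(
        param_name=param_name, values=grid, rss=rss, tss=tss, flat_bound=flat_bound
    )


def decompose_alignment_terms(params: GelParameters, data) -> dict:
    """Split the steady-state identity for Q into its four mechanistic terms.

    Returns profiles (NaN at the two endpoints, where centred differences are
    undefined): ``compression`` -(beta_tau/2) dv/dx, ``advection``
    -tau v dQ/dx, ``diffusion`` ell^2 d2Q/dx2, ``active``
    lambda'tau (c/c0) Q, and their ``total``.  When Q was produced by
    :func:`solve_steady_Q` on the same grid the total reproduces Q exactly at
    every interior point.
    """
    if isinstance(data, EmbryoDataset):
        x, v, dvdx, Q, c = data.x, data.v, data.dvdx, data.Q, data.c
    else:
        x, v, dvdx, Q = (np.asarray(a, float) for a in data[:4])
        c = np.asarray(data[4], float) if len(data) > 4 and data[4] is not None else None
    dx = _check_grid(x)
    dQ = np.full_like(Q, np.nan)
    d2Q = np.full_like(Q, np.nan)
    dQ[1:-1] = (Q[2:] - Q[:-2]) / (2 * dx)
    d2Q[1:-1] = (Q[2:] - 2 * Q[1:-1] + Q[:-2]) / dx**2

    compression = -0.5 * params.beta_tau * dvdx
    advection = -params.tau * v * dQ
    diffusion = params.ell**2 * d2Q
    if c is not None and params.lambda_tau > 0:
        active = params.lambda_tau * (c / np.mean(c)) * Q
    else:
        active = np.zeros_like(Q)
    total = compression + advection + diffusion + active
    return {
        "x": x,
        "compression": compression,
        "advection": advection,
        "diffusion": diffusion,
        "active": active,
        "total": total,
    }
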