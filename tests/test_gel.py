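"""Gel solvers and parameter fitting: closed forms, oracles, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from nemacortex import studies
from nemacortex.datasets import EmbryoDataset
from nemacortex.errors import FitError, InstabilityError, InvalidParameterError
from nemacortex.gel import (
    GelParameters,
    bootstrap_parameters,
    decompose_alignment_terms,
    fit_gel_parameters,
    identifiability_scan,
    simulate_Q_dynamics,
    solve_steady_Q,
)
from nemacortex.synth import generate_embryo_dataset


def shooting_oracle(x, v_fun, dvdx_fun, params, n_eval=2001):
    """Independent BVP solution by shooting: integrate the steady-state ODE
    ell^2 Q'' = tau v Q' + Q + (beta_tau/2) v' from the left edge with two
    initial slopes and combine linearly to match the right boundary."""

    def rhs(s, y):
        q, dq = y
        return [dq, (params.tau * v_fun(s) * dq + q
                     + 0.5 * params.beta_tau * dvdx_fun(s)) / params.ell**2]

    def integrate(q0, dq0, homogeneous):
        def rhs_h(s, y):
            q, dq = y
            return [dq, (params.tau * v_fun(s) * dq + q) / params.ell**2]
        sol = solve_ivp(
            rhs_h if homogeneous else rhs,
            (x[0], x[-1]),
            [q0, dq0],
            t_eval=x,
            rtol=1e-10,
            atol=1e-12,
            method="RK45",
        )
        assert sol.success
        return sol.y[0]

    q_part = integrate(params.C1, 0.0, homogeneous=False)
    q_hom = integrate(0.0, 1.0, homogeneous=True)
    slope = (params.C2 - q_part[-1]) / q_hom[-1]
    return q_part + slope * q_hom


class TestSolveSteady:
    def test_uniform_compression_closed_form(self, ap_grid):
        # v = -k x gives the constant solution Q = beta_tau * k / 2
        k, beta_tau = 0.4, 0.6
        q_const = beta_tau * k / 2
        params = GelParameters(tau=1.3, beta_tau=beta_tau, ell=2.0,
                               C1=q_const, C2=q_const)
        Q = solve_steady_Q(ap_grid, -k * ap_grid, np.full_like(ap_grid, -k), params)
        assert np.allclose(Q, 0.12, atol=1e-6)

    def test_zero_flow_zero_boundaries(self, ap_grid):
        params = GelParameters(tau=1.0, beta_tau=0.5, ell=2.0)
        Q = solve_steady_Q(ap_grid, np.zeros_like(ap_grid),
                           np.zeros_like(ap_grid), params)
        assert np.allclose(Q, 0.0, atol=1e-12)

    def test_matches_shooting_integrator(self, ap_grid, cytokinesis_truth):
        # independent fine-grid shooting oracle on the analytic flow
        peak, width = -5.0, 4.33

        def v_fun(s):
            return peak * np.exp(-(s**2) / (2 * width**2))

        def dvdx_fun(s):
            return peak * (-s / width**2) * np.exp(-(s**2) / (2 * width**2))

        Q = solve_steady_Q(ap_grid, v_fun(ap_grid), dvdx_fun(ap_grid),
                           cytokinesis_truth, max_dx=0.05)
        Q_oracle = shooting_oracle(ap_grid, v_fun, dvdx_fun, cytokinesis_truth)
        assert np.max(np.abs(Q - Q_oracle)) < 1e-4

    def test_instability_raises(self, ap_grid, cytokinesis_flow_field):
        f = cytokinesis_flow_field
        c = 1.0 + np.exp(-ap_grid**2 / 8)
        params = GelParameters(tau=2.0, beta_tau=0.6, ell=2.0, lambda_tau=2.0)
        with pytest.raises(InstabilityError):
            solve_steady_Q(ap_grid, f.v, f.dvdx, params, c=c)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        c1=st.floats(-0.3, 0.3),
        c2=st.floats(-0.3, 0.3),
        scale=st.floats(0.1, 3.0),
    )
    def test_affine_in_boundaries_linear_in_beta(self, c1, c2, scale):
        # solution = particular(beta_tau) + C1*H1 + C2*H2, checked numerically
        x = studies.ap_grid()
        from nemacortex.synth import generate_flow_profile

        f = generate_flow_profile(studies.cytokinesis_flow())

        def solve(beta_tau, b1, b2):
            p = GelParameters(tau=1.5, beta_tau=beta_tau, ell=2.0, C1=b1, C2=b2)
            return solve_steady_Q(x, f.v, f.dvdx, p)

        base = solve(0.5, 0.0, 0.0)
        h1 = solve(0.0, 1.0, 0.0)
        h2 = solve(0.0, 0.0, 1.0)
        combined = scale * base + c1 * h1 + c2 * h2
        direct = solve(0.5 * scale, c1, c2)
        assert np.allclose(direct, combined, atol=1e-10)


class TestDynamics:
    def test_relaxation_closed_form(self, ap_grid):
        # v = 0, negligible diffusion: uniform Q decays as exp(-t/tau)
        params = GelParameters(tau=2.0, beta_tau=0.0, ell=1e-3)
        zeros = np.zeros_like(ap_grid)
        _, traj = simulate_Q_dynamics(ap_grid, zeros, zeros, params,
                                      np.full_like(ap_grid, 0.3),
                                      dt=0.002, t_end=2.0, store_every=1000)
        mid = traj[-1][ap_grid.size // 2]
        assert mid == pytest.approx(0.3 * np.exp(-1.0), rel=1e-2)

    def test_converges_to_steady(self, ap_grid, cytokinesis_flow_field,
                                 cytokinesis_truth):
        f = cytokinesis_flow_field
        steady = solve_steady_Q(ap_grid, f.v, f.dvdx, cytokinesis_truth)
        _, traj = simulate_Q_dynamics(ap_grid, f.v, f.dvdx, cytokinesis_truth,
                                      np.zeros_like(ap_grid), dt=0.02,
                                      t_end=60.0, store_every=500)
        assert np.max(np.abs(traj[-1] - steady)) < 1e-4

    def test_advection_limit_preserves_bump(self, ap_grid):
        # tau -> inf, ell -> 0, uniform v: a bump advects at speed v
        params = GelParameters(tau=1e7, beta_tau=0.0, ell=1e-3)
        v = np.full_like(ap_grid, 2.0)
        Q0 = np.exp(-((ap_grid + 5) ** 2) / 2)
        _, traj = simulate_Q_dynamics(ap_grid, v, np.zeros_like(ap_grid),
                                      params, Q0, dt=0.05, t_end=2.0,
                                      store_every=100)
        Q = traj[-1]
        com = float((ap_grid * Q).sum() / Q.sum())
        assert com == pytest.approx(-1.0, abs=0.1)
        # shape preserved up to numerical diffusion
        assert Q.max() > 0.5 * Q0.max()

    def test_cfl_violation_raises(self, ap_grid):
        params = GelParameters(tau=1.0, beta_tau=0.0, ell=1.0)
        v = np.full_like(ap_grid, 10.0)
        with pytest.raises(InvalidParameterError, match="CFL"):
            simulate_Q_dynamics(ap_grid, v, np.zeros_like(ap_grid), params,
                                np.zeros_like(ap_grid), dt=1.0, t_end=2.0)


class TestFit:
    def test_noiseless_cytokinesis_recovery(self, cytokinesis_truth):
        ds = generate_embryo_dataset(cytokinesis_truth,
                                     studies.cytokinesis_flow())[0]
        fit = fit_gel_parameters(ds)
        assert fit.params.tau == pytest.approx(2.34, rel=0.02)
        assert fit.params.beta_tau == pytest.approx(0.654, rel=0.02)
        assert fit.params.ell == pytest.approx(1.69, rel=0.02)
        assert not fit.tau_unbounded_below

    def test_weak_advection_tau_bound(self, pseudocleavage_truth):
        ds = generate_embryo_dataset(pseudocleavage_truth,
                                     studies.pseudocleavage_flow())[0]
        fit = fit_gel_parameters(ds)
        assert fit.tau_unbounded_below
        assert fit.tau_bound == 0.5
        assert fit.tau_report == "< 0.5 (n.d.)"
        # the identifiable parameters are still recovered
        assert fit.params.beta_tau == pytest.approx(0.6, rel=0.02)
        assert fit.params.ell == pytest.approx(4.7, rel=0.02)

    def test_lambda_recovery_and_active_term(self):
        truth = studies.cytokinesis_active_truth()
        ds = generate_embryo_dataset(truth, studies.cytokinesis_flow(),
                                     myosin=studies.cytokinesis_myosin())[0]
        fit = fit_gel_parameters(ds, include_lambda=True)
        assert fit.params.lambda_tau == pytest.approx(0.34, rel=0.1)
        # lambda'tau = 0 makes the active decomposition vanish identically
        no_lambda = GelParameters(tau=2.34, beta_tau=0.654, ell=1.69)
        terms = decompose_alignment_terms(no_lambda, ds)
        assert np.all(terms["active"] == 0)

    def test_ci_covers_truth_on_noisy_replicates(self, cytokinesis_truth):
        # simulation calibration: 95% CI for beta_tau and ell covers the
        # truth in >= 90% of replicates (10 embryos, Q noise sd 0.02)
        hits_bt = hits_ell = 0
        n_rep = 50
        for rep in range(n_rep):
            embryos = generate_embryo_dataset(
                cytokinesis_truth, studies.cytokinesis_flow(),
                noise_sigma_Q=0.02, n_embryos=10, seed=1000 + rep,
            )
            from nemacortex.datasets import average_datasets

            fit = fit_gel_parameters(average_datasets(embryos), n_starts=4)
            lo, hi = fit.ci95["beta_tau"]
            hits_bt += lo <= 0.654 <= hi
            lo, hi = fit.ci95["ell"]
            hits_ell += lo <= 1.69 <= hi
        assert hits_bt >= 0.9 * n_rep
        assert hits_ell >= 0.9 * n_rep

    def test_degenerate_input_raises(self, ap_grid):
        zeros = np.zeros_like(ap_grid)
        ds = EmbryoDataset(x=ap_grid, v=zeros, dvdx=zeros, Q=zeros)
        with pytest.raises(FitError):
            fit_gel_parameters(ds)


class TestBootstrap:
    def test_identical_noiseless_embryos_zero_width(self, cytokinesis_truth):
        embryos = generate_embryo_dataset(cytokinesis_truth,
                                          studies.cytokinesis_flow(),
                                          n_embryos=3)
        with pytest.warns(UserWarning):
            boot = bootstrap_parameters(embryos, n_boot=8, seed=5, n_starts=2)
        assert boot.low_n_boot_warning
        lo, hi = boot.interval["ell"]
        assert hi - lo < 1e-6
        assert boot.median["ell"] == pytest.approx(1.69, rel=0.01)

    def test_deterministic_under_seed(self, cytokinesis_truth):
        embryos = generate_embryo_dataset(cytokinesis_truth,
                                          studies.cytokinesis_flow(),
                                          noise_sigma_Q=0.02, n_embryos=4,
                                          seed=2)
        with pytest.warns(UserWarning):
            b1 = bootstrap_parameters(embryos, n_boot=10, seed=9, n_starts=2)
        with pytest.warns(UserWarning):
            b2 = bootstrap_parameters(embryos, n_boot=10, seed=9, n_starts=2)
        assert b1.median == b2.median
        assert b1.interval == b2.interval

    def test_median_close_to_full_fit(self, cytokinesis_truth):
        embryos = generate_embryo_dataset(cytokinesis_truth,
                                          studies.cytokinesis_flow(),
                                          noise_sigma_Q=0.01, n_embryos=8,
                                          seed=3)
        from nemacortex.datasets import average_datasets

        full = fit_gel_parameters(average_datasets(embryos), n_starts=4)
        boot = bootstrap_parameters(embryos, n_boot=100, seed=4, n_starts=2)
        for name in ("beta_tau", "ell"):
            assert boot.median[name] == pytest.approx(
                getattr(full.params, name), rel=0.05
            )


class TestIdentifiability:
    def test_weak_advection_flat_below_bound(self, pseudocleavage_truth):
        ds = generate_embryo_dataset(pseudocleavage_truth,
                                     studies.pseudocleavage_flow())[0]
        fit = fit_gel_parameters(ds)
        grid = np.geomspace(0.05, 0.5, 10)
        scan = identifiability_scan(ds, "tau", grid, fit.params)
        # residuals indistinguishable (normalised change < 1%) for tau < 0.5
        assert np.all(scan.normalized_rss <= 0.01)
        assert scan.flat_bound == pytest.approx(0.5)

    def test_cytokinesis_convex_around_optimum(self, cytokinesis_truth):
        ds = generate_embryo_dataset(cytokinesis_truth,
                                     studies.cytokinesis_flow())[0]
        grid = np.linspace(2.34 * 0.5, 2.34 * 1.5, 11)
        scan = identifiability_scan(ds, "tau", grid, cytokinesis_truth)
        i_min = int(np.argmin(scan.rss))
        assert grid[i_min] == pytest.approx(2.34, rel=0.11)
        assert np.all(np.diff(scan.rss[: i_min + 1]) <= 0)
        assert np.all(np.diff(scan.rss[i_min:]) >= 0)

    def test_single_point_grid(self, cytokinesis_truth):
        ds = generate_embryo_dataset(cytokinesis_truth,
                                     studies.cytokinesis_flow())[0]
        scan = identifiability_scan(ds, "tau", [2.34], cytokinesis_truth)
        assert scan.rss.shape == (1,)
        assert scan.rss[0] < 1e-12


class TestDecomposition:
    def test_terms_sum_to_Q(self):
        truth = studies.cytokinesis_active_truth()
        ds = generate_embryo_dataset(truth, studies.cytokinesis_flow(),
                                     myosin=studies.cytokinesis_myosin())[0]
        terms = decompose_alignment_terms(truth, ds)
        assert np.max(np.abs(terms["total"][1:-1] - ds.Q[1:-1])) < 1e-8

    def test_active_peak_below_compression_peak(self):
        # at the cytokinesis lambda'tau the active contribution stays small
        # compared to compression-based alignment
        truth = studies.cytokinesis_active_truth()
        ds = generate_embryo_dataset(truth, studies.cytokinesis_flow(),
                                     myosin=studies.cytokinesis_myosin())[0]
        terms = decompose_alignment_terms(truth, ds)
        assert np.nanmax(terms["active"]) < np.nanmax(terms["compression"])
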