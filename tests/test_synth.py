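"""Synthetic meshworks, flows and embryo datasets: determinism and fidelity."""

import numpy as np
import pytest

from nemacortex import studies
from nemacortex.errors import InvalidParameterError
from nemacortex.gel import solve_steady_Q
from nemacortex.synth import (
    FlowProfileSpec,
    MeshworkParams,
    MyosinBandSpec,
    advect_image,
    generate_embryo_dataset,
    generate_filament_image,
    generate_flow_profile,
    sample_start_angles,
)


class TestMeshwork:
    def test_same_seed_identical(self):
        p = MeshworkParams(bias_B=1.0, seed=42)
        a = generate_filament_image(p)
        b = generate_filament_image(MeshworkParams(bias_B=1.0, seed=42))
        assert np.array_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_filament_image(MeshworkParams(seed=1))
        b = generate_filament_image(MeshworkParams(seed=2))
        assert not np.array_equal(a, b)

    def test_zero_bias_uniform_start_angles(self, rng):
        # B = 0: starting angles carry no net nematic order
        theta = sample_start_angles(20000, 0.0, rng)
        qxx = np.mean(np.cos(2 * theta))
        qxy = np.mean(np.sin(2 * theta))
        assert abs(qxx) < 0.02 and abs(qxy) < 0.02

    def test_bias_concentrates_toward_vertical(self, rng):
        theta = sample_start_angles(20000, 2.0, rng)
        # vertical concentration: Qxx = <cos 2theta> strongly negative
        assert np.mean(np.cos(2 * theta)) < -0.5

    @pytest.mark.parametrize(
        "bad",
        [
            dict(snr=0.0),
            dict(snr=-1.0),
            dict(n_filaments=0),
            dict(image_size=(0, 64)),
            dict(bias_B=-0.5),
        ],
    )
    def test_invalid_params_raise(self, bad):
        with pytest.raises(InvalidParameterError):
            MeshworkParams(**bad)

    def test_snr_definition(self):
        # (peak - background mean) / background sd matches the request
        img = generate_filament_image(MeshworkParams(seed=0, snr=8.0))
        background_mean = np.median(img)  # filaments cover little area
        peak = img.max()
        assert (peak - background_mean) / 1.0 == pytest.approx(8.0, rel=0.3)


class TestFlowProfiles:
    def test_gaussian_bump_peak(self, ap_grid):
        spec = FlowProfileSpec(shape="gaussian_bump", peak_velocity=-5.0,
                               width=4.0, grid=ap_grid)
        f = generate_flow_profile(spec)
        assert f.v.min() == pytest.approx(-5.0)
        assert ap_grid[np.argmin(f.v)] == pytest.approx(0.0)

    def test_linear_slope(self, ap_grid):
        spec = FlowProfileSpec(shape="linear", peak_velocity=-0.4, width=1.0,
                               grid=ap_grid)
        f = generate_flow_profile(spec)
        assert np.allclose(f.dvdx, -0.4)

    @pytest.mark.parametrize("shape", ["gaussian_bump", "tanh_front", "linear"])
    def test_derivative_integrates_back(self, shape, ap_grid):
        spec = FlowProfileSpec(shape=shape, peak_velocity=-3.0, width=3.0,
                               grid=studies.ap_grid(dx=0.01))
        f = generate_flow_profile(spec)
        # trapezoid oracle: cumulative integral of dvdx reproduces v
        v_rec = f.v[0] + np.concatenate(
            [[0.0], np.cumsum((f.dvdx[1:] + f.dvdx[:-1]) / 2 * np.diff(f.x))]
        )
        assert np.max(np.abs(v_rec - f.v)) < 1e-4

    def test_invalid_width_raises(self, ap_grid):
        with pytest.raises(InvalidParameterError):
            FlowProfileSpec(shape="gaussian_bump", peak_velocity=-5.0,
                            width=0.0, grid=ap_grid)


class TestAdvection:
    def test_zero_flow_identity(self, ap_grid):
        img = generate_filament_image(MeshworkParams(seed=3))
        spec = FlowProfileSpec(shape="linear", peak_velocity=0.0, width=1.0,
                               grid=ap_grid)
        out = advect_image(img, generate_flow_profile(spec), dt=1.0,
                           pixel_size=0.1)
        assert np.allclose(out, img, atol=1e-8)

    def test_uniform_shift_exact(self):
        img = generate_filament_image(MeshworkParams(seed=4))
        grid = np.linspace(-20, 20, 11)
        # uniform v with v*dt = 3 px = 0.3 um
        spec = FlowProfileSpec(shape="tanh_front", peak_velocity=0.0,
                               width=1.0, grid=grid)
        f = generate_flow_profile(spec)
        f.v[:] = 0.3
        f.dvdx[:] = 0.0
        out = advect_image(img, f, dt=1.0, pixel_size=0.1)
        assert np.allclose(out[:, 10:-10], img[:, 7:-13], atol=1e-6)

    def test_linear_flow_matches_pointwise_displacement(self):
        # dense-grid interpolation oracle for a linearly varying flow
        h = w = 128
        yy, xx = np.indices((h, w))
        img = np.sin(2 * np.pi * xx / 16.0) + 0.3 * np.sin(2 * np.pi * yy / 23.0)
        grid = np.linspace(-10, 10, 201)
        spec = FlowProfileSpec(shape="linear", peak_velocity=0.5, width=1.0,
                               grid=grid)
        f = generate_flow_profile(spec)
        out = advect_image(img, f, dt=1.0, pixel_size=0.1)
        # oracle: sample the original at the exactly inverted source position
        x_um = (np.arange(w) - (w - 1) / 2) * 0.1
        # x_dest = x_src * exp(k dt) for linear v = k x is not needed at
        # first order; invert numerically on a dense grid
        x_dense = np.linspace(x_um[0] - 1, x_um[-1] + 1, 20001)
        x_image = x_dense + 0.5 * x_dense * 1.0  # v = 0.5 x, dt = 1
        src_um = np.interp(x_um, x_image, x_dense)
        src_px = src_um / 0.1 + (w - 1) / 2
        from scipy.ndimage import map_coordinates

        oracle = map_coordinates(
            img, np.meshgrid(np.arange(h, dtype=float), src_px, indexing="ij"),
            order=3, mode="nearest",
        )
        interior = (slice(10, -10), slice(10, -10))
        assert np.max(np.abs(out[interior] - oracle[interior])) < 0.05

    def test_excessive_displacement_raises(self):
        img = np.zeros((32, 32))
        grid = np.linspace(-10, 10, 11)
        spec = FlowProfileSpec(shape="linear", peak_velocity=0.0, width=1.0,
                               grid=grid)
        f = generate_flow_profile(spec)
        f.v[:] = 100.0
        with pytest.raises(InvalidParameterError):
            advect_image(img, f, dt=1.0, pixel_size=0.1)


class TestEmbryoDatasets:
    def test_zero_noise_equals_solver(self, cytokinesis_truth):
        ds = generate_embryo_dataset(cytokinesis_truth,
                                     studies.cytokinesis_flow())[0]
        Q = solve_steady_Q(ds.x, ds.v, ds.dvdx, cytokinesis_truth)
        assert np.array_equal(ds.Q, Q)
        assert ds.truth is cytokinesis_truth

    def test_noise_sd_matches_request(self, cytokinesis_truth):
        sigma = 0.02
        embryos = generate_embryo_dataset(cytokinesis_truth,
                                          studies.cytokinesis_flow(),
                                          noise_sigma_Q=sigma, n_embryos=10,
                                          seed=11)
        stack = np.stack([e.Q for e in embryos])
        per_point_sd = stack.std(axis=0, ddof=1)
        assert 0.015 < per_point_sd.mean() < 0.025

    def test_same_seed_identical(self, cytokinesis_truth):
        kw = dict(noise_sigma_Q=0.02, n_embryos=3, seed=7)
        a = generate_embryo_dataset(cytokinesis_truth,
                                    studies.cytokinesis_flow(), **kw)
        b = generate_embryo_dataset(cytokinesis_truth,
                                    studies.cytokinesis_flow(), **kw)
        for e1, e2 in zip(a, b):
            assert np.array_equal(e1.Q, e2.Q)

    def test_dvdx_consistent_with_v(self, cytokinesis_truth):
        ds = generate_embryo_dataset(cytokinesis_truth,
                                     studies.cytokinesis_flow())[0]
        num = np.gradient(ds.v, ds.x)
        assert np.max(np.abs(num[2:-2] - ds.dvdx[2:-2])) < 5e-3

    def test_myosin_band_shape(self):
        band = MyosinBandSpec(baseline=1.0, amplitude=1.0, width=4.0)
        x = studies.ap_grid()
        c = band.evaluate(x)
        assert c.max() == pytest.approx(2.0)
        assert c[0] == pytest.approx(1.0, abs=1e-2)
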