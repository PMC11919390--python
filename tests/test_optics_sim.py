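"""Refraction ray tracing and PSF machinery."""

import math

import numpy as np
import pytest

from condrop import optics_sim, shapes, synth_data
from condrop.optics_sim import (
    OpticalConfig,
    convolve_with_psf,
    extract_apparent_profile,
    measure_psf_proxy,
    model_psf,
    render_apparent_image,
    snell_refract,
)


class TestSnell:
    def test_normal_incidence_unchanged(self):
        d, tir = snell_refract([0.0, 0.0, 1.0], [0.0, 0.0, 1.0], 1.518, 1.334)
        assert not tir
        np.testing.assert_allclose(d, [0.0, 0.0, 1.0], atol=1e-12)

    def test_oil_to_buffer_45deg(self):
        s, c = math.sin(math.radians(45)), math.cos(math.radians(45))
        d, tir = snell_refract([s, 0.0, c], [0.0, 0.0, -1.0], 1.518, 1.334)
        assert not tir
        angle = math.degrees(math.asin(abs(d[0])))
        assert angle == pytest.approx(53.6, abs=0.1)

    def test_total_internal_reflection(self):
        s, c = math.sin(math.radians(80)), math.cos(math.radians(80))
        d, tir = snell_refract([s, 0.0, c], [0.0, 0.0, -1.0], 1.518, 1.334)
        assert tir and d is None

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            snell_refract([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], 1.5, 1.3)

    def test_reversibility(self):
        """Tracing the refracted ray backwards recovers the incident one."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            n = np.array([0.0, 0.0, 1.0])
            out, tir = snell_refract(d, n, 1.334, 1.518)
            if tir:
                continue
            back, tir2 = snell_refract(-out, n, 1.518, 1.334)
            assert not tir2
            np.testing.assert_allclose(back, -d, atol=1e-9)


class TestApparentImage:
    def test_index_matched_boundary_is_true_boundary(self):
        cap = shapes.SphericalCap(theta_deg=110.0, r_contact=8.0)
        cfg = OpticalConfig(n_buffer=1.518, n_condensate=1.518, grid=0.25)
        img = render_apparent_image(cap, cfg)
        prof = extract_apparent_profile(img)
        assert prof.z_max == pytest.approx(cap.height, abs=2 * cfg.grid)
        zi = np.linspace(0.3, cap.height - 0.6, 40)
        true_prof = shapes.cap_profile(cap, 400)
        r_true = np.interp(zi, true_prof.z, true_prof.r)
        r_app = np.interp(zi, prof.z, prof.r)
        assert np.max(np.abs(r_app - r_true)) <= 1.5 * cfg.grid

    def test_lateral_extent_preserved_at_base(self):
        cap = shapes.SphericalCap(theta_deg=110.0, r_contact=10.0)
        cfg = OpticalConfig(n_condensate=1.33, grid=0.25)
        img = render_apparent_image(cap, cfg)
        prof = extract_apparent_profile(img)
        assert prof.r[0] == pytest.approx(cap.r_contact, abs=cfg.grid)

    def test_aqueous_cap_appears_stretched(self):
        cap = shapes.SphericalCap(theta_deg=120.0, r_contact=10.0)
        cfg = OpticalConfig(n_condensate=1.33, grid=0.3)
        img = render_apparent_image(cap, cfg)
        prof = extract_apparent_profile(img)
        ratio = prof.z_max / cap.height
        assert 1.1 <= ratio <= 1.3


class TestAxialScale:
    def test_index_matched_factor_is_unity(self):
        cfg = OpticalConfig(n_buffer=1.518, n_condensate=1.518, grid=0.3)
        factor = optics_sim.apparent_axial_scale(
            cfg, true_thetas=(90.0, 120.0), radii=(12.0,)
        )
        assert factor == pytest.approx(1.0, abs=0.02)


class TestModelPSF:
    def test_sums_to_one_and_fwhm_ratio(self):
        psf = model_psf(sigma_lateral=0.2, sigma_axial=0.6, spacing=(0.05, 0.05, 0.05))
        assert psf.grid.sum() == pytest.approx(1.0, abs=1e-9)
        cz, cy, cx = psf.center
        lat = optics_sim._fwhm(psf.grid[cz, cy, :]) * psf.spacing[0]
        ax = optics_sim._fwhm(psf.grid[:, cy, cx]) * psf.spacing[2]
        assert ax / lat == pytest.approx(3.0, rel=0.02)

    def test_second_moments_match_sigma(self):
        sig_l, sig_a = 0.3, 0.9
        psf = model_psf(sig_l, sig_a, spacing=(0.1, 0.1, 0.1))
        z, y, x = np.indices(psf.grid.shape).astype(float)
        for axis, c, d, sig in [
            (x, psf.center[2], 0.1, sig_l),
            (z, psf.center[0], 0.1, sig_a),
        ]:
            var = float((psf.grid * ((axis - c) * d) ** 2).sum())
            assert var == pytest.approx(sig**2, rel=0.01)

    def test_small_extent_logs_warning(self, caplog):
        with caplog.at_level("WARNING"):
            model_psf(0.2, 0.6, spacing=(0.1, 0.1, 0.1), extent=(0.6, 0.6, 1.8))
        assert any("6 sigma" in m for m in caplog.messages)


def _gaussian_bead_stack(center, sigma=(2.0, 1.2, 1.2), shape=(41, 31, 31),
                         amp=500.0, bg=20.0):
    z, y, x = np.indices(shape).astype(float)
    cz, cy, cx = center
    g = amp * np.exp(
        -((z - cz) ** 2 / (2 * sigma[0] ** 2)
          + (y - cy) ** 2 / (2 * sigma[1] ** 2)
          + (x - cx) ** 2 / (2 * sigma[2] ** 2))
    )
    return synth_data.Stack3D(
        voxels={"fluorescence": g + bg, "reflection": np.zeros(shape)},
        spacing=(0.1, 0.1, 0.1), base_index=0,
    )


class TestMeasurePSF:
    def test_recovers_gaussian_width(self):
        stack = _gaussian_bead_stack((20.0, 15.0, 15.0))
        psf = measure_psf_proxy([stack], bead_diameter=0.1, window=(25, 19, 19))
        assert psf.grid.sum() == pytest.approx(1.0, abs=1e-6)
        z, y, x = np.indices(psf.grid.shape).astype(float)
        var_z = float((psf.grid * (z - psf.center[0]) ** 2).sum())
        assert math.sqrt(var_z) == pytest.approx(2.0, rel=0.1)

    def test_shifted_copies_average_to_single(self):
        stacks = [
            _gaussian_bead_stack((20.0 + dz, 15.0, 15.0))
            for dz in (-0.4, -0.2, 0.0, 0.2, 0.4)
        ]
        avg = measure_psf_proxy(stacks, 0.1, window=(25, 19, 19))
        single = measure_psf_proxy([stacks[2]], 0.1, window=(25, 19, 19))
        assert np.max(np.abs(avg.grid - single.grid)) < 5e-3

    def test_no_spots_raises(self):
        flat = synth_data.Stack3D(
            voxels={"fluorescence": np.zeros((10, 10, 10)),
                    "reflection": np.zeros((10, 10, 10))},
            spacing=(0.1, 0.1, 0.1), base_index=0,
        )
        with pytest.raises(ValueError):
            measure_psf_proxy([flat], 0.1)


class TestConvolve:
    def _stack(self, arr):
        return synth_data.Stack3D(
            voxels={"fluorescence": arr, "reflection": np.zeros_like(arr)},
            spacing=(0.1, 0.1, 0.1), base_index=0,
        )

    def _delta_psf(self):
        g = np.zeros((3, 3, 3))
        g[1, 1, 1] = 1.0
        return optics_sim.PSF(grid=g, spacing=(0.1, 0.1, 0.1), center=(1, 1, 1))

    def test_delta_identity(self, rng):
        arr = rng.uniform(0, 10, (12, 12, 12))
        out = convolve_with_psf(self._stack(arr), self._delta_psf())
        np.testing.assert_allclose(out.voxels["fluorescence"], arr, atol=1e-12)

    def test_intensity_conserved(self, rng):
        # keep the kernel support inside the volume so no energy leaves
        arr = np.zeros((24, 24, 24))
        arr[9:15, 9:15, 9:15] = rng.uniform(0, 10, (6, 6, 6))
        psf = model_psf(0.1, 0.15, spacing=(0.1, 0.1, 0.1))
        out = convolve_with_psf(self._stack(arr), psf)
        assert out.voxels["fluorescence"].sum() == pytest.approx(
            arr.sum(), rel=1e-6
        )

    def test_matches_direct_triple_sum(self, rng):
        """FFT-based linear convolution equals the brute-force sum."""
        arr = rng.uniform(0, 1, (16, 16, 16))
        g = rng.uniform(0, 1, (3, 3, 3))
        g /= g.sum()
        psf = optics_sim.PSF(grid=g, spacing=(0.1, 0.1, 0.1), center=(1, 1, 1))
        out = convolve_with_psf(self._stack(arr), psf).voxels["fluorescence"]
        brute = np.zeros_like(arr)
        pad = np.pad(arr, 1)
        for dz in range(3):
            for dy in range(3):
                for dx in range(3):
                    brute += g[dz, dy, dx] * pad[
                        2 - dz:2 - dz + 16, 2 - dy:2 - dy + 16, 2 - dx:2 - dx + 16
                    ]
        np.testing.assert_allclose(out, brute, rtol=1e-10, atol=1e-12)

    def test_spacing_mismatch_raises(self, rng):
        arr = rng.uniform(0, 1, (8, 8, 8))
        psf = model_psf(0.1, 0.2, spacing=(0.2, 0.2, 0.2))
        with pytest.raises(ValueError):
            convolve_with_psf(self._stack(arr), psf)


class TestBufferIndexMonotonicity:
    def test_smaller_index_mismatch_gives_factor_closer_to_unity(self):
        """Raising the buffer index toward the oil's shrinks the focal
        shift, so the fitted rescale factor moves toward 1."""
        panel = dict(true_thetas=(100.0, 120.0), radii=(12.0,))
        strong = optics_sim.apparent_axial_scale(
            OpticalConfig(n_condensate=1.41), **panel)
        weak = optics_sim.apparent_axial_scale(
            OpticalConfig(n_buffer=1.45, n_condensate=1.45), **panel)
        assert abs(weak - 1.0) < abs(strong - 1.0)
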