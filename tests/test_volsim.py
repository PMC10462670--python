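"""Synthetic scene generation: rasterization oracles, PSF shape, degradation."""

import numpy as np
import pytest

from isorestore.metrics import fwhm
from isorestore.volsim import (SimSpec, degrade_volume, gaussian_psf,
                               generate_bead_volume, generate_tube_volume,
                               make_care_pairs, make_semisynthetic_pairs,
                               rasterize_sphere, rasterize_tube)
from isorestore.volume import PSFKernel, Volume3D


class TestBeads:
    def test_deterministic_under_seed(self):
        spec = SimSpec(kind="beads", shape=(24, 24, 24), n_objects=5, seed=3)
        a = generate_bead_volume(spec)
        b = generate_bead_volume(spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_empty_scene_is_all_zero(self):
        spec = SimSpec(kind="beads", shape=(16, 16, 16), n_objects=0, seed=0)
        assert not generate_bead_volume(spec).data.any()

    def test_sphere_rasterization_matches_brute_force(self):
        """Foreground voxels are exactly those satisfying the sphere inequality."""
        vol = np.zeros((16, 16, 16), dtype=np.float32)
        center = np.array([7.3, 8.1, 6.9])
        rasterize_sphere(vol, center, radius=3.0, intensity=200.0)
        for z in range(16):
            for y in range(16):
                for x in range(16):
                    inside = ((z - center[0]) ** 2 + (y - center[1]) ** 2
                              + (x - center[2]) ** 2) <= 9.0
                    assert (vol[z, y, x] == 200.0) == inside

    def test_intensities_within_range_and_background_zero(self):
        spec = SimSpec(kind="beads", shape=(32, 32, 32), n_objects=8,
                       intensity_range=(150, 255), seed=1)
        vol = generate_bead_volume(spec)
        fg = vol.data[vol.data > 0]
        assert fg.size and fg.min() >= 150 and fg.max() <= 255

    def test_overlap_combines_by_maximum(self):
        vol = np.zeros((9, 9, 9), dtype=np.float32)
        rasterize_sphere(vol, np.array([4.0, 4.0, 4.0]), 2.0, 100.0)
        rasterize_sphere(vol, np.array([4.0, 4.0, 5.0]), 2.0, 180.0)
        assert vol.max() == 180.0  # never the sum

    @pytest.mark.parametrize("kwargs", [
        dict(shape=(6, 6, 6), radius_range=(2.0, 4.0)),   # radius > shape/4
        dict(n_objects=-1),
        dict(radius_range=(0.5, 2.0)),
        dict(intensity_range=(-5.0, 10.0)),
    ])
    def test_parameter_errors(self, kwargs):
        base = dict(kind="beads", shape=(32, 32, 32), n_objects=3, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            generate_bead_volume(SimSpec(**base))

    def test_fullscale_spec_accepted(self):
        spec = SimSpec(kind="beads", shape=(512, 512, 512), n_objects=800,
                       radius_range=(2, 4), intensity_range=(150, 255), seed=0)
        assert spec.n_objects == 800  # validation passes; not generated here


class TestTubes:
    def test_deterministic_and_empty(self):
        spec = SimSpec(kind="tubes", shape=(24, 24, 24), n_objects=3, seed=5)
        a, b = generate_tube_volume(spec), generate_tube_volume(spec)
        np.testing.assert_array_equal(a.data, b.data)
        empty = SimSpec(kind="tubes", shape=(16, 16, 16), n_objects=0, seed=0)
        assert not generate_tube_volume(empty).data.any()

    def test_straight_tube_cross_sections_are_discs(self):
        """Each interior cross-section equals a brute-force rasterized disc."""
        vol = np.zeros((21, 21, 32), dtype=np.float32)
        path = np.array([[10.0, 10.0, 4.0], [10.0, 10.0, 27.0]])  # along x
        r = 3.0
        rasterize_tube(vol, path, radius=r, intensity=120.0)
        yy, zz = np.meshgrid(np.arange(21), np.arange(21))
        disc = ((zz - 10.0) ** 2 + (yy - 10.0) ** 2) <= r * r
        for x in range(8, 24):  # away from the hemispherical caps
            np.testing.assert_array_equal(vol[:, :, x] == 120.0, disc)

    def test_kind_mismatch_rejected(self):
        spec = SimSpec(kind="beads", shape=(16, 16, 16), n_objects=1, seed=0)
        with pytest.raises(ValueError):
            generate_tube_volume(spec)


class TestGaussianPSF:
    def test_unit_sum_and_centered(self):
        psf = gaussian_psf(0.3, 1.0, spacing=0.2, support=25)
        assert psf.data.sum() == pytest.approx(1.0, abs=1e-9)
        assert psf.is_centered

    def test_fwhm_identity_sigma_two_voxels(self):
        # FWHM = 2 sqrt(2 ln 2) sigma = 4.71 voxels for sigma = 2
        spacing = 0.2
        fwhm_um = 2.0 * spacing * 2.3548
        psf = gaussian_psf(fwhm_um, fwhm_um, spacing, support=31)
        profile = psf.data[:, 15, 15]
        assert fwhm(profile) == pytest.approx(4.71, rel=0.02)

    def test_anisotropy_ratio_matches_quoted_widths(self):
        """305 nm lateral / 1000 nm axial renders at the stated 1000/305 ratio.

        Rendered at 50 nm voxels so both widths are adequately sampled for
        the sub-pixel FWHM measurement.
        """
        psf = gaussian_psf(0.305, 1.0, spacing=0.05, support=81)
        ax = fwhm(psf.data[:, 40, 40], spacing=0.05)
        lat = fwhm(psf.data[40, 40, :], spacing=0.05)
        assert ax / lat == pytest.approx(1000.0 / 305.0, rel=0.02)

    def test_even_support_rejected_small_support_warns(self):
        with pytest.raises(ValueError):
            gaussian_psf(0.3, 1.0, 0.2, support=24)
        with pytest.warns(UserWarning):
            gaussian_psf(0.3, 3.0, 0.2, support=11)


class TestDegrade:
    def test_delta_psf_identity(self, small_bead_volume):
        delta = np.zeros((3, 3, 3))
        delta[1, 1, 1] = 1.0
        out = degrade_volume(small_bead_volume, PSFKernel(delta, (0.2,) * 3), 1)
        np.testing.assert_allclose(out.data, small_bead_volume.data, atol=1e-4)

    def test_z_subsampling_arithmetic(self):
        vol = Volume3D(np.random.default_rng(0).uniform(0, 1, (128, 8, 8)),
                       (0.2, 0.2, 0.2))
        delta = np.zeros((1, 1, 1))
        delta[0, 0, 0] = 1.0
        out = degrade_volume(vol, PSFKernel(delta, (0.2,) * 3), z_factor=4)
        assert out.shape == (32, 8, 8)
        assert out.spacing[0] == pytest.approx(0.8)

    def test_matches_brute_force_convolution(self, rng):
        gt = Volume3D(rng.uniform(0, 1, (16, 16, 16)), (1.0, 1.0, 1.0))
        k = rng.uniform(0, 1, (5, 5, 5))
        psf = PSFKernel(k, (1.0, 1.0, 1.0))
        out = degrade_volume(gt, psf, 1).data
        padded = np.pad(gt.data, 2, mode="reflect")
        ref = np.zeros((16, 16, 16))
        kn = psf.data[::-1, ::-1, ::-1]  # true convolution flips the kernel
        for z in range(16):
            for y in range(16):
                for x in range(16):
                    ref[z, y, x] = np.sum(padded[z:z + 5, y:y + 5, x:x + 5] * kn)
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_intensity_conservation_reflective_edges(self):
        # content away from the borders: reflection then conserves total mass
        vol = np.zeros((32, 48, 48), dtype=np.float32)
        rng = np.random.default_rng(9)
        for _ in range(8):
            c = rng.uniform(12, np.array([20, 36, 36]))
            rasterize_sphere(vol, c, rng.uniform(1.5, 3.0), 200.0)
        v = Volume3D(vol, (0.2, 0.2, 0.2))
        psf = gaussian_psf(0.4, 1.0, 0.2, support=15)
        out = degrade_volume(v, psf, 1)
        assert out.data.sum() == pytest.approx(v.data.sum(), rel=5e-3)

    def test_degradation_broadens_by_quadrature(self):
        """Axial width of a degraded small bead follows the quadrature sum."""
        vol = np.zeros((64, 32, 32), dtype=np.float32)
        rasterize_sphere(vol, np.array([32.0, 16.0, 16.0]), 1.0, 200.0)
        v = Volume3D(vol, (0.2, 0.2, 0.2))
        raw_w = fwhm(v.data[:, 16, 16].astype(float))
        psf_fwhm_vox = 8.0
        psf = gaussian_psf(0.2 * 2.0, 0.2 * psf_fwhm_vox, 0.2, support=41)
        out = degrade_volume(v, psf, 1)
        blurred_w = fwhm(out.data[:, 16, 16].astype(float))
        assert blurred_w >= raw_w
        predicted = np.hypot(raw_w, psf_fwhm_vox)
        assert blurred_w == pytest.approx(predicted, rel=0.10)

    def test_z_factor_exceeding_extent_rejected(self, small_bead_volume):
        psf = gaussian_psf(0.3, 0.3, 0.2, support=5)
        with pytest.raises(ValueError):
            degrade_volume(small_bead_volume, psf, z_factor=1000)


class TestSemisyntheticPairs:
    def test_noop_degradation(self, rng):
        slices = rng.uniform(0, 1, (3, 24, 24)).astype(np.float32)
        degraded, target = make_semisynthetic_pairs(slices, sigma=0.0, factor=1)
        np.testing.assert_allclose(degraded, target, atol=1e-7)
        np.testing.assert_allclose(target, slices, atol=1e-7)

    def test_column_matches_independent_1d_oracle(self, rng):
        """One column equals 1D Gaussian conv + area subsample + cubic interp
        computed by an independent in-test implementation."""
        from scipy.interpolate import CubicSpline

        slices = rng.uniform(0, 1, (1, 40, 8))
        sigma, factor = 2.0, 4
        degraded, _ = make_semisynthetic_pairs(slices, sigma, factor)
        # edge-mirrored Gaussian convolution, column by column
        radius = int(4.0 * sigma + 0.5)
        kk = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        kk /= kk.sum()
        blurred = np.stack([
            np.convolve(np.pad(slices[0, :, c], radius, mode="symmetric"),
                        kk, mode="valid")
            for c in range(8)
        ], axis=1)
        # exact area averaging over factor-sized cells
        low = blurred.reshape(10, factor, 8).mean(axis=1)
        # cubic re-interpolation on the cell-centre grid, range-clipped
        coords = (np.arange(40) + 0.5) * (10 / 40) - 0.5
        ref = CubicSpline(np.arange(10), low[:, 3])(np.clip(coords, 0, 9))
        ref = np.clip(ref, low.min(), low.max())
        np.testing.assert_allclose(degraded[0, :, 3], ref, atol=1e-5)

    def test_care_recipe_is_sigma3_factor5(self, rng):
        slices = rng.uniform(0, 1, (2, 30, 16)).astype(np.float32)
        care_d, care_t = make_care_pairs(slices)
        semi_d, semi_t = make_semisynthetic_pairs(slices, sigma=3.0, factor=5)
        np.testing.assert_array_equal(care_d, semi_d)
        np.testing.assert_array_equal(care_t, semi_t)

    def test_empty_slice_set_rejected(self):
        with pytest.raises(ValueError):
            make_semisynthetic_pairs(np.empty((0, 8, 8)))
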