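"""Orientation estimation, CAS, vernier detection and the starlet filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from sarcomech.datatypes import ImageStack, OrientationField
from sarcomech.morphometry import (
    analyze_stack,
    axial_difference_deg,
    compute_cas,
    compute_orientation_field,
    compute_vd,
    denoise_wavelet,
    detect_verniers,
    estimate_main_axis,
    estimate_main_axis_geometric,
    stretch_correct_vd,
)
from sarcomech.phantom import FiberPhantomSpec, generate_fiber_stack


def grating(angle_deg: float, sl_um: float = 2.5, n: int = 256, px: float = 0.25):
    """Plain cosine grating with striation normal at ``angle_deg``."""
    xs = (np.arange(n) + 0.5) * px
    yy, xx = np.meshgrid(xs, xs, indexing="ij")
    k = 2 * np.pi / sl_um
    a = np.deg2rad(angle_deg)
    return 100.0 * (1.0 + 0.5 * np.cos(k * (xx * np.cos(a) + yy * np.sin(a))))


class TestStarletDenoise:
    def test_constant_image_unchanged(self):
        stack = ImageStack(np.full((1, 64, 64), 7.0), 0.25, 1.0)
        out = denoise_wavelet(stack, n_scales=3, threshold_k=3.0)
        assert np.allclose(out.voxels, 7.0)

    def test_zero_threshold_reconstructs_exactly(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(10, 100, (1, 96, 96))
        stack = ImageStack(img, 0.25, 1.0)
        out = denoise_wavelet(stack, n_scales=4, threshold_k=0.0)
        assert np.allclose(out.voxels, img, rtol=1e-6)

    def test_noise_reduction_on_striation(self):
        clean = grating(0.0, n=256)[None]
        rng = np.random.default_rng(3)
        noisy = np.clip(clean + rng.normal(0, 10.0, clean.shape), 0, None)
        out = denoise_wavelet(ImageStack(noisy, 0.25, 1.0), n_scales=4, threshold_k=3.0)
        rms_in = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_out = np.sqrt(np.mean((out.voxels - clean) ** 2))
        assert rms_out < rms_in

    def test_mean_preserved(self):
        clean = grating(10.0, n=128)[None]
        rng = np.random.default_rng(4)
        noisy = np.clip(clean + rng.normal(0, 5.0, clean.shape), 0, None)
        out = denoise_wavelet(ImageStack(noisy, 0.25, 1.0), n_scales=3, threshold_k=3.0)
        assert abs(out.voxels.mean() - noisy.mean()) / noisy.mean() < 1e-3

    def test_excessive_scales_rejected(self):
        stack = ImageStack(np.ones((1, 32, 32)), 0.25, 1.0)
        with pytest.raises(ValueError, match="scales"):
            denoise_wavelet(stack, n_scales=6)


class TestOrientationField:
    def test_grating_normal_recovered(self):
        f = compute_orientation_field(grating(30.0), scale_um=0.625, pixel_size_um=0.25)
        th2 = np.deg2rad(2 * f.theta_deg[f.mask])
        mode = 0.5 * np.degrees(np.arctan2(np.sin(th2).mean(), np.cos(th2).mean()))
        assert abs(mode - 30.0) < 1.0

    def test_rotation_equivariance(self):
        img0 = grating(0.0, n=256)
        img45 = ndimage.rotate(img0, -45.0, reshape=False, order=3, mode="nearest")
        f = compute_orientation_field(img45, scale_um=0.625, pixel_size_um=0.25)
        c = np.s_[64:192, 64:192]
        dev = axial_difference_deg(f.theta_deg[c][f.mask[c]], 45.0)
        assert np.median(np.abs(dev)) < 2.0

    def test_flat_image_gives_empty_mask(self):
        f = compute_orientation_field(np.zeros((64, 64)), scale_um=1.0, pixel_size_um=0.25)
        assert f.n_valid == 0

    def test_scale_below_two_pixels_rejected(self):
        with pytest.raises(ValueError, match="2 pixels"):
            compute_orientation_field(grating(0.0), scale_um=0.3, pixel_size_um=0.25)


class TestMainAxis:
    def test_uniform_field(self):
        theta = np.full((32, 32), 25.0)
        f = OrientationField(theta, np.ones_like(theta), np.ones_like(theta, dtype=bool))
        assert estimate_main_axis(f) == pytest.approx(25.0)

    def test_symmetric_populations_cancel(self):
        """+40 and -40 deg at equal energy average to 0 (doubled-angle sum)."""
        theta = np.concatenate([np.full(50, 40.0), np.full(50, -40.0)]).reshape(10, 10)
        f = OrientationField(theta, np.ones_like(theta), np.ones_like(theta, dtype=bool))
        assert estimate_main_axis(f) == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(-80.0, 80.0), st.floats(-40.0, 40.0))
    @settings(max_examples=25, deadline=None)
    def test_shift_equivariance(self, base, shift):
        rng = np.random.default_rng(12)
        theta = base + rng.normal(0, 5.0, (16, 16))
        theta = (theta + 90.0) % 180.0 - 90.0
        f1 = OrientationField(theta, np.ones_like(theta), np.ones_like(theta, dtype=bool))
        shifted = (theta + shift + 90.0) % 180.0 - 90.0
        f2 = OrientationField(shifted, np.ones_like(theta), np.ones_like(theta, dtype=bool))
        d = (estimate_main_axis(f2) - estimate_main_axis(f1) - shift) % 180.0
        assert min(d, 180.0 - d) < 1e-6

    def test_empty_mask_raises(self):
        theta = np.zeros((8, 8))
        f = OrientationField(theta, np.zeros_like(theta), np.zeros_like(theta, dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            estimate_main_axis(f)

    def test_geometric_axis_on_rotated_fiber(self):
        spec = FiberPhantomSpec(
            orientation_dispersion_deg=20.0, field_size_um=(80.0, 80.0),
            main_axis_deg=30.0, seed=3,
        )
        stack, _ = generate_fiber_stack(spec)
        assert estimate_main_axis_geometric(stack) == pytest.approx(30.0, abs=1.0)


class TestCAS:
    def test_parallel_field_is_one(self):
        theta = np.zeros((32, 32))
        f = OrientationField(theta, np.ones_like(theta), np.ones_like(theta, dtype=bool))
        assert compute_cas(f, 0.0) == pytest.approx(1.0)

    def test_uniform_deviations_give_two_over_pi(self, rng):
        n = 100_000
        theta = rng.uniform(-90.0, 90.0, n).reshape(200, 500)
        f = OrientationField(theta, np.ones_like(theta), np.ones_like(theta, dtype=bool))
        assert compute_cas(f, 0.0) == pytest.approx(2 / np.pi, abs=0.01)

    def test_symmetric_sixty_degree_deviations(self):
        theta = np.concatenate([np.full(50, 60.0), np.full(50, -60.0)]).reshape(10, 10)
        f = OrientationField(theta, np.ones_like(theta), np.ones_like(theta, dtype=bool))
        assert compute_cas(f, 0.0) == pytest.approx(0.5)

    def test_intensity_affine_invariance(self, parallel_stack):
        stack, _ = parallel_stack
        img = stack.voxels[0]
        f1 = compute_orientation_field(img, 0.625, 0.25)
        f2 = compute_orientation_field(3.0 * img + 50.0, 0.625, 0.25)
        ax = 0.0
        assert compute_cas(f2, ax) == pytest.approx(compute_cas(f1, ax), abs=1e-6)

    def test_stack_cas_is_pixel_weighted_slice_mean(self):
        spec = FiberPhantomSpec(
            orientation_dispersion_deg=10.0, field_size_um=(60.0, 60.0),
            n_slices=3, z_step_um=5.0, seed=6,
        )
        stack, _ = generate_fiber_stack(spec)
        r = analyze_stack(stack, sl_um=2.5)
        expected = np.average(r.per_slice["cas"], weights=r.per_slice["n_pixels"])
        assert r.cas == pytest.approx(float(expected), rel=1e-12)


class TestVernierDetection:
    def test_clean_phantom_has_no_verniers(self, parallel_stack):
        stack, _ = parallel_stack
        r = analyze_stack(stack, sl_um=2.5)
        assert len(r.vernier_coords) == 0

    def test_eight_dislocations_detected_near_truth(self, dislocation_slice):
        stack, truth = dislocation_slice
        r = analyze_stack(stack, sl_um=2.5)
        assert abs(len(r.vernier_coords) - 8) <= 1
        det = np.array([c[:2] for c in r.vernier_coords])
        for tx, ty, _ in truth.dislocation_coords:
            d = np.hypot(det[:, 0] - tx, det[:, 1] - ty)
            assert d.min() < 2.5  # within one SL of an inserted defect

    def test_sensitivity_under_noise(self):
        """Recall >= 0.8 with read noise at 10% of the modulation amplitude."""
        hits = total = 0
        for seed in (101, 102, 103):
            spec = FiberPhantomSpec(
                field_size_um=(200.0, 200.0), pixel_size_um=0.195,
                fiber_diameter_um=60.0, n_dislocations=8,
                orientation_dispersion_deg=5.0, read_sigma=5.0, seed=seed,
            )
            stack, truth = generate_fiber_stack(spec)
            r = analyze_stack(stack, sl_um=2.5)
            det = np.array([c[:2] for c in r.vernier_coords]) if r.vernier_coords else np.empty((0, 2))
            for tx, ty, _ in truth.dislocation_coords:
                total += 1
                if len(det) and np.hypot(det[:, 0] - tx, det[:, 1] - ty).min() < 2.5:
                    hits += 1
        assert hits / total >= 0.8

    def test_sl_out_of_range_rejected(self, parallel_stack):
        stack, _ = parallel_stack
        with pytest.raises(ValueError, match="range"):
            detect_verniers(stack, [], sl_um=5.0)


class TestVernierDensity:
    def test_density_arithmetic(self):
        coords = [(float(i), 0.0, 0.0) for i in range(8)]
        assert compute_vd(coords, 40_000.0) == pytest.approx(0.02)
        assert compute_vd([], 40_000.0) == 0.0

    def test_halving_area_doubles_density(self):
        coords = [(1.0, 1.0, 0.0)] * 4
        assert compute_vd(coords, 500.0) == pytest.approx(2 * compute_vd(coords, 1000.0))

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            compute_vd([], 0.0)

    def test_stretch_correction_values(self):
        assert stretch_correct_vd(0.10, 2.4, 2.4) == pytest.approx(0.10)
        assert stretch_correct_vd(0.10, 3.6, 2.4) == pytest.approx(0.15)

    def test_stretch_correction_on_resampled_phantom(self):
        """Stretching a phantom 1.5x dilutes VD; the correction recovers it."""
        spec = FiberPhantomSpec(
            sarcomere_length_um=2.4, field_size_um=(200.0, 100.0),
            fiber_diameter_um=60.0, n_dislocations=16,
            orientation_dispersion_deg=3.0, seed=13,
        )
        stack, truth = generate_fiber_stack(spec)
        r0 = analyze_stack(stack, sl_um=2.4, use_frame_area=True)
        stretched = ndimage.zoom(stack.voxels, (1.0, 1.0, 1.5), order=1)
        stretched = np.clip(stretched[:, :, : stack.voxels.shape[2]], 0, None)
        sstack = ImageStack(stretched, stack.pixel_size_um, stack.z_step_um)
        r1 = analyze_stack(sstack, sl_um=3.6, use_frame_area=True)
        corrected = stretch_correct_vd(r1.vd_per_100um2, 3.6, 2.4)
        assert corrected == pytest.approx(r0.vd_per_100um2, rel=0.20)
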