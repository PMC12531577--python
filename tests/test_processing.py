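"""Quadrant handling, registration, measurements, stitching, filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from multiplane25d import processing as proc
from multiplane25d import scene as sc, splitter as sp
from multiplane25d import imager
from multiplane25d.imager import NoiseModel
from multiplane25d.processing import StitchThresholds


@pytest.fixture(scope="module")
def bead_plane_images(optics_small, focus_psf_small):
    """Four per-plane bead images of one field, plane 1 shifted (3.2, -1.7) px."""
    cfg = sp.SplitterConfig(
        quadrant_shape_px=(300, 300), sensor_shape_px=(600, 600),
        injected_misregistration=((0, 0), (3.2, -1.7), (0, 0), (0, 0)))
    px = optics_small.pixel_size_sample
    scene = sc.make_bead_monolayer(25, extent=(300 * px, 300 * px),
                                   z_plane=0.0, seed=5, min_separation=2.0)
    planes = []
    for p in range(4):
        frame = imager.render_quadframe(
            scene, cfg, focus_psf_small, optics_small, NoiseModel(),
            seed=100 + p, stage_z=cfg.plane_centers[p], out_of_range="skip")
        planes.append(proc.split_quadrants(frame, cfg)[p].astype(float))
    return planes, cfg


class TestSplitQuadrants:
    def test_split_then_assemble_is_identity(self, splitter_300):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 1000, splitter_300.sensor_shape_px).astype(np.uint16)
        planes = proc.split_quadrants(frame, splitter_300)
        back = proc.assemble_quadrants(planes, splitter_300)
        assert np.array_equal(back, frame)

    def test_output_order_follows_plane_labels(self, splitter_300):
        # permute quadrant placement; order must stay Z0-4 ... Z12-16
        origins = splitter_300.quadrant_origins_px
        shuffled = splitter_300.replace(
            quadrant_origins_px=(origins[2], origins[0], origins[3], origins[1]))
        frame = np.zeros(shuffled.sensor_shape_px, dtype=np.uint16)
        h, w = shuffled.quadrant_shape_rc
        for p, (r0, c0) in enumerate(shuffled.quadrant_origins_px):
            frame[r0:r0 + h, c0:c0 + w] = 10 * (p + 1)
        subs = proc.split_quadrants(frame, shuffled)
        for p, sub in enumerate(subs):
            assert np.all(sub == 10 * (p + 1))

    def test_shape_mismatch_rejected(self, splitter_300):
        with pytest.raises(ValueError):
            proc.split_quadrants(np.zeros((100, 100), np.uint16), splitter_300)


class TestRegistration:
    def test_injected_misregistration_recovered(self, bead_plane_images):
        planes, cfg = bead_plane_images
        reg = proc.calibrate_registration(planes)
        dx, dy = reg.shifts[1]
        assert abs(dx - 3.2) <= 0.2 and abs(dy - (-1.7)) <= 0.2

    def test_null_case_and_reference_shift(self, bead_plane_images):
        planes, cfg = bead_plane_images
        reg = proc.calibrate_registration(planes)
        assert reg.shifts[3] == (0.0, 0.0)
        for p in (0, 2):
            assert np.hypot(*reg.shifts[p]) <= 0.1

    def test_too_few_beads_raises_with_count(self):
        rng = np.random.default_rng(1)
        imgs = [rng.normal(100, 1, (200, 200)) for _ in range(4)]
        with pytest.raises(proc.CalibrationError, match=r"\d+ beads"):
            proc.calibrate_registration(imgs)

    def test_apply_integer_shift_exact_in_interior(self):
        rng = np.random.default_rng(2)
        img = rng.random((50, 60))
        reg = proc.RegistrationMap(reference=1,
                                   shifts=((2.0, -3.0), (0.0, 0.0)))
        out = proc.apply_registration([img, img], reg)
        # translation by -(dy, dx) = (+3, -2): out[r, c] = img[r - 3, c + 2]
        np.testing.assert_array_equal(out[0][3:50, 0:58], img[0:47, 2:60])
        np.testing.assert_array_equal(out[1], img)

    def test_apply_then_negation_restores_image(self):
        # band-limited test image: interpolation can only invert content
        # below Nyquist, which microscope images (PSF-limited) satisfy
        rng = np.random.default_rng(0)
        img = ndimage.gaussian_filter(rng.normal(0, 1, (100, 100)), 2) * 100 + 500
        fwd = proc.RegistrationMap(reference=1, shifts=((1.3, -0.6), (0.0, 0.0)))
        back = proc.RegistrationMap(reference=1, shifts=((-1.3, 0.6), (0.0, 0.0)))
        out = proc.apply_registration(
            proc.apply_registration([img, img], fwd), back)
        # stay clear of the fill strips plus the cubic spline's support
        interior = (slice(8, -8), slice(8, -8))
        scale = img.max() - img.min()
        assert np.max(np.abs(out[0][interior] - img[interior])) < 1e-3 * scale

    def test_residual_after_registration_below_a_third_pixel(self,
                                                             bead_plane_images):
        planes, cfg = bead_plane_images
        reg = proc.calibrate_registration(planes)
        aligned = proc.apply_registration(planes, reg)
        reg2 = proc.calibrate_registration(list(aligned))
        assert max(np.hypot(*s) for s in reg2.shifts) < 0.3


class TestMeasureFwhm:
    def test_exact_gaussian_both_methods(self):
        x = np.arange(-6.0, 6.0, 0.01)
        y = np.exp(-0.5 * x ** 2)
        for method in ("gaussian_fit", "halfmax_interp"):
            res = proc.measure_fwhm(y, coords=x, method=method)
            assert res["fwhm"] == pytest.approx(2.354820045, abs=1e-4)
            assert res["method"] == method

    def test_noisy_profile_monte_carlo_mean(self):
        x = np.arange(-6.0, 6.0, 0.05)
        clean = np.exp(-0.5 * x ** 2)
        rng = np.random.default_rng(0)
        fwhms = [proc.measure_fwhm(clean + rng.normal(0, 0.05, x.size),
                                   coords=x)["fwhm"] for _ in range(50)]
        assert np.mean(fwhms) == pytest.approx(2.3548, rel=0.02)

    def test_2d_image_lateral_and_axial_cuts(self):
        yy, xx = np.mgrid[0:61, 0:61]
        img = np.exp(-0.5 * (((xx - 30) / 6.0) ** 2 + ((yy - 30) / 3.0) ** 2))
        lat = proc.measure_fwhm(img, pitch=0.1, axis="lateral")["fwhm"]
        axl = proc.measure_fwhm(img, pitch=0.1, axis="axial")["fwhm"]
        assert lat == pytest.approx(2.3548 * 0.6, rel=1e-3)
        assert axl == pytest.approx(2.3548 * 0.3, rel=1e-3)

    def test_flat_profile_rejected(self):
        with pytest.raises(Exception):
            proc.measure_fwhm(np.ones(50), pitch=0.1)


class TestInterplaneSpacing:
    def test_spacing_passthrough_with_2um_splitter(self, optics_small,
                                                   scan_psf_small):
        """Reconfiguring the splitter to dz = 2 um halves the spacings."""
        from multiplane25d import workflows as wf
        cfg = sp.SplitterConfig(plane_centers=(1.0, 3.0, 5.0, 7.0),
                                plane_span=2.0,
                                quadrant_shape_px=(260, 260),
                                sensor_shape_px=(520, 520))
        report = wf.characterize_interplane(optics_small, cfg, NoiseModel(),
                                            n_beads=15, z_step=0.25, seed=2,
                                            psf=scan_psf_small)
        assert report["mean_spacing_um"] == pytest.approx(2.0, abs=0.15)

    def test_coarse_scan_step_rejected(self):
        zscan = proc.BeadZScan(stage_z=np.arange(0, 16, 1.0),
                               intensities=(np.zeros((3, 16)),))
        with pytest.raises(ValueError):
            proc.measure_interplane_spacing(zscan)


class TestProjections:
    def test_constant_stack(self):
        stack = np.full((5, 8, 8), 3.5)
        np.testing.assert_array_equal(proc.project(stack, "AIP"), stack[0])
        np.testing.assert_array_equal(proc.project(stack, "MIP"), stack[0])

    def test_mip_dominates_aip(self):
        stack = np.random.default_rng(3).random((10, 16, 16))
        assert np.all(proc.project(stack, "MIP") >= proc.project(stack, "AIP"))

    def test_grouped_aip_matches_bruteforce(self):
        stack = np.random.default_rng(4).random((64, 6, 6))
        aips = proc.grouped_aip(stack, 16)
        assert aips.shape[0] == 4
        for k in range(4):
            np.testing.assert_array_equal(
                aips[k], stack[16 * k:16 * (k + 1)].mean(axis=0))


class TestDepthCode:
    def test_single_active_plane_takes_its_palette_color(self):
        planes = [np.zeros((10, 10)) for _ in range(4)]
        planes[2][4, 4] = 5.0
        rgb, legend = proc.depth_code(planes)
        np.testing.assert_allclose(rgb[4, 4], proc.DEFAULT_DEPTH_PALETTE[2])
        assert rgb[0, 0].sum() == 0

    def test_all_zero_planes_give_black(self):
        rgb, _ = proc.depth_code([np.zeros((5, 5))] * 4)
        assert np.all(rgb == 0)

    def test_palette_size_mismatch(self):
        with pytest.raises(ValueError):
            proc.depth_code([np.zeros((5, 5))] * 4,
                            palette=[(1, 0, 0), (0, 1, 0)])

    def test_nuclei_dominant_color_matches_ground_truth_plane(self):
        """Closed loop against scene labels: the dominant color of each
        nucleus matches the plane holding most of its emitters (>= 95%)."""
        scene, labels, table = sc.make_nuclei_phantom(
            15, extent=(60, 60), depth_range=(1.0, 15.0), seed=8,
            voxel_size=0.5)
        cfg = sp.default_quadplane_config()
        # plane images from the label volume: voxel counts per depth interval
        zc = (np.arange(labels.shape[0]) + 0.5) * 0.5
        planes = []
        for p in range(4):
            lo, hi = cfg.depth_interval(p)
            sel = (zc >= lo) & (zc < hi)
            planes.append((labels[sel] > 0).sum(axis=0).astype(float))
        rgb, _ = proc.depth_code(planes)
        palette = np.asarray(proc.DEFAULT_DEPTH_PALETTE)
        hits, assigned = 0, 0
        for r in table.itertuples():
            footprint = (labels == r.id).any(axis=0)
            mean_rgb = rgb[footprint].mean(axis=0)
            color_plane = int(np.argmax(palette @ mean_rgb /
                                        np.linalg.norm(palette, axis=1)))
            # ground truth: the plane holding most of this nucleus's volume;
            # a nucleus split ~evenly across a boundary has no known plane
            zz, _, _ = np.nonzero(labels == r.id)
            votes = np.array([sp.plane_for_depth(cfg, d)
                              for d in (zz + 0.5) * 0.5])
            counts = np.bincount(votes, minlength=4)
            if counts.max() < 0.6 * len(votes):
                continue
            assigned += 1
            hits += color_plane == int(np.argmax(counts))
        assert assigned >= 10
        assert hits / assigned >= 0.95


class TestStitchGrid:
    @staticmethod
    def _texture(seed=0, shape=(600, 600)):
        rng = np.random.default_rng(seed)
        return ndimage.gaussian_filter(rng.normal(0, 1, shape), 3) * 50 + 100

    def test_two_tiles_known_offset_recovered(self):
        big = self._texture()
        tile = 200
        a = big[:tile, :tile]
        b = ndimage.shift(big, (-3.0, -(180 - 2.0)), order=1)[:tile, :tile]
        _, table = proc.stitch_grid([a, b], np.array([(0.0, 0.0), (0.0, 180.0)]))
        d = table[["stitched_row", "stitched_col"]].to_numpy()
        rec = d[1] - d[0]
        assert np.hypot(rec[0] - 3.0, rec[1] - 178.0) <= 0.5

    def test_pure_noise_overlap_falls_back_to_nominal(self):
        tiles = [np.random.default_rng(k).normal(0, 1, (200, 200))
                 for k in range(2)]
        _, table = proc.stitch_grid(tiles, np.array([(0.0, 0.0), (0.0, 180.0)]))
        assert table.had_fallback_link.all()
        np.testing.assert_allclose(
            table[["stitched_row", "stitched_col"]].to_numpy(),
            [[0, 0], [0, 180]], atol=1e-9)

    def test_single_tile_identity(self):
        tile = self._texture(shape=(64, 64))
        mosaic, table = proc.stitch_grid([tile], np.array([(0.0, 0.0)]))
        np.testing.assert_array_equal(mosaic, tile)

    def test_3x3_grid_rms_below_half_pixel(self):
        big = self._texture(1)
        tile, step = 200, 180
        rng = np.random.default_rng(5)
        tiles, nominal, true = [], [], []
        for gr in range(3):
            for gc in range(3):
                jr, jc = (0.0, 0.0) if (gr, gc) == (0, 0) else rng.uniform(-4, 4, 2)
                r0, c0 = gr * step + jr, gc * step + jc
                t = ndimage.shift(big, (-r0, -c0), order=1)[:tile, :tile]
                tiles.append(t + rng.normal(0, 0.5, t.shape))
                nominal.append((gr * step, gc * step))
                true.append((r0, c0))
        _, table = proc.stitch_grid(tiles, np.asarray(nominal))
        est = table[["stitched_row", "stitched_col"]].to_numpy()
        err = est - np.asarray(true)
        err -= err.mean(axis=0)
        assert np.sqrt((err ** 2).sum(axis=1).mean()) <= 0.5


class TestBilateralFilter:
    def test_constant_image_unchanged_exactly(self):
        img = np.full((40, 40), 7.25)
        np.testing.assert_array_equal(proc.bilateral_filter(img, 2.0, 5.0), img)

    def test_large_sigma_range_limit_is_gaussian_blur(self):
        rng = np.random.default_rng(0)
        img = ndimage.gaussian_filter(rng.random((80, 80)), 1.0)
        ours = proc.bilateral_filter(img, 2.0, 1e9)
        ref = ndimage.gaussian_filter(img, 2.0, truncate=3.0, mode="reflect")
        assert np.max(np.abs(ours - ref)) / np.abs(ref).max() < 1e-3

    def test_edge_preserved_and_noise_suppressed(self):
        rng = np.random.default_rng(1)
        img = np.zeros((60, 120))
        img[:, 60:] = 10.0
        noisy = img + rng.normal(0, 0.5, img.shape)
        bil = proc.bilateral_filter(noisy, 2.0, 2.0)
        gau = ndimage.gaussian_filter(noisy, 2.0, truncate=3.0, mode="reflect")

        def edge_width(im):
            prof = im[:, 30:90].mean(axis=0)
            lo, hi = prof[0] + 0.1 * 10, prof[0] + 0.9 * 10
            return np.argmax(prof > hi) - np.argmax(prof > lo)

        assert edge_width(bil) <= edge_width(gau)
        flat = (slice(10, 50), slice(5, 40))
        assert noisy[flat].var() / bil[flat].var() >= 4.0


class TestChromaticShift:
    def test_null_and_injected_shift_recovered(self, optics_small,
                                               focus_psf_small):
        from multiplane25d import workflows as wf
        cfg = sp.SplitterConfig(quadrant_shape_px=(300, 300),
                                sensor_shape_px=(600, 600))
        null = wf.chromatic_shift_report(optics_small, cfg, NoiseModel(),
                                         psf=focus_psf_small,
                                         channel_shift=(0.0, 0.0),
                                         n_beads=25, seed=9)
        assert np.all(np.hypot(null.dx_px, null.dy_px) < 0.1)
        injected = wf.chromatic_shift_report(
            optics_small, cfg, NoiseModel(), psf=focus_psf_small,
            channel_shift=(0.054, 0.0324), n_beads=25, seed=9)
        assert np.all(np.abs(injected.dx_px - 0.5) < 0.1)
        assert np.all(np.abs(injected.dy_px - 0.3) < 0.1)

    def test_invariant_to_brightness_rescaling(self):
        rng = np.random.default_rng(2)
        img0 = np.zeros((120, 120))
        for x, y in rng.uniform(12, 108, (15, 2)):
            yy, xx = np.mgrid[0:120, 0:120]
            img0 += 500 * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / 4.0)
        img1 = ndimage.shift(img0, (0.3, 0.5), order=3)
        a = proc.measure_chromatic_shift([img0], [img1], min_beads=10)
        b = proc.measure_chromatic_shift([img0 * 3.0], [img1 * 3.0],
                                         min_beads=10)
        np.testing.assert_allclose(a[["dx_px", "dy_px"]],
                                   b[["dx_px", "dy_px"]], atol=1e-9)

    def test_too_few_beads_raises(self):
        with pytest.raises(proc.CalibrationError):
            proc.measure_chromatic_shift([np.zeros((50, 50))],
                                         [np.zeros((50, 50))])
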