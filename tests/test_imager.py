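"""Forward model: plane rendering, quad frames, z-stacks, grids, noise."""

import numpy as np
import pytest

from multiplane25d import imager, scene as sc, splitter as sp
from multiplane25d.imager import NoiseModel, apply_camera_noise
from multiplane25d.processing import split_quadrants


def single_bead_scene(x, y, z, extent=(20.0, 20.0), brightness=2000.0,
                      background=0.0):
    return sc.Scene(emitters=[sc.Emitter(x=x, y=y, z=z, brightness=brightness)],
                    extent=extent, thickness=16.0, background_rate=background)


class TestCameraNoise:
    def test_zero_photons_zero_read_noise_gives_offset(self):
        noise = NoiseModel(read_noise=0.0)
        img = apply_camera_noise(np.zeros((32, 32)), noise, seed=0)
        assert np.all(img == 100)

    def test_uniform_field_moments(self):
        noise = NoiseModel()
        photons = np.full((512, 512), 1000.0)
        img = apply_camera_noise(photons, noise, seed=1).astype(float)
        mean_expected = noise.gain * noise.quantum_efficiency * 1000 + noise.offset
        assert img.mean() == pytest.approx(mean_expected, rel=0.01)
        # (variance - read-noise term) / (mean - offset) estimates the gain
        var = img.var()
        gain_est = (var - noise.gain ** 2 * noise.read_noise ** 2) / \
            (img.mean() - noise.offset)
        assert gain_est == pytest.approx(noise.gain, rel=0.05)

    def test_same_seed_bit_identical(self):
        photons = np.random.default_rng(0).uniform(0, 500, (64, 64))
        a = apply_camera_noise(photons, NoiseModel(), seed=42)
        b = apply_camera_noise(photons, NoiseModel(), seed=42)
        assert np.array_equal(a, b)

    def test_negative_photons_rejected(self):
        with pytest.raises(ValueError):
            apply_camera_noise(np.full((4, 4), -1.0), NoiseModel(), 0)


class TestRenderPlane:
    def test_single_emitter_peak_near_true_position(self, optics_small,
                                                    focus_psf_small):
        s = single_bead_scene(10.0, 8.0, 5.0)
        img = imager.render_plane(s, focus_psf_small, 5.0, optics_small,
                                  shape_px=(160, 160))
        r, c = np.unravel_index(np.argmax(img), img.shape)
        px = optics_small.pixel_size_sample
        assert abs((c + 0.5) * px - 10.0) <= px
        assert abs((r + 0.5) * px - 8.0) <= px

    def test_linearity_two_emitters(self, optics_small, focus_psf_small):
        a = single_bead_scene(8.0, 8.0, 5.0)
        b = single_bead_scene(12.0, 11.0, 5.0)
        both = sc.Scene(emitters=a.emitters + b.emitters, extent=(20, 20),
                        thickness=16.0, background_rate=0.0)
        kw = dict(shape_px=(160, 160))
        img = imager.render_plane(both, focus_psf_small, 5.0, optics_small, **kw)
        img_a = imager.render_plane(a, focus_psf_small, 5.0, optics_small, **kw)
        img_b = imager.render_plane(b, focus_psf_small, 5.0, optics_small, **kw)
        np.testing.assert_array_equal(img, img_a + img_b)

    def test_homogeneity_in_brightness(self, optics_small, focus_psf_small):
        dim = single_bead_scene(10, 10, 5.0, brightness=1000, background=7.0)
        bright = single_bead_scene(10, 10, 5.0, brightness=2000, background=7.0)
        kw = dict(shape_px=(120, 120))
        i1 = imager.render_plane(dim, focus_psf_small, 5.0, optics_small, **kw)
        i2 = imager.render_plane(bright, focus_psf_small, 5.0, optics_small, **kw)
        np.testing.assert_allclose(i2 - 7.0, 2.0 * (i1 - 7.0),
                                   rtol=1e-12, atol=1e-12)

    def test_out_of_range_defocus_raises(self, optics_small, focus_psf_small):
        s = single_bead_scene(10, 10, 15.0)
        with pytest.raises(imager.DefocusRangeError):
            imager.render_plane(s, focus_psf_small, 5.0, optics_small,
                                shape_px=(64, 64))


class TestQuadFrame:
    def test_bead_brightest_in_its_own_quadrant(self, optics_small,
                                                scan_psf_small, splitter_300):
        s = single_bead_scene(16.0, 16.0, 2.0, extent=(32.4, 32.4),
                              background=0.0)
        photons = imager.render_quadframe_photons(
            s, splitter_300, scan_psf_small, optics_small, out_of_range="skip")
        peaks = [sub.max() for sub in split_quadrants(photons, splitter_300)]
        assert int(np.argmax(peaks)) == 0
        second = sorted(peaks)[-2]
        assert peaks[0] / second > 1.5

    def test_flipped_plane_appears_row_mirrored(self, optics_small,
                                                scan_psf_small, splitter_300):
        s = single_bead_scene(10.0, 5.0, 14.0, extent=(32.4, 32.4))
        photons = imager.render_quadframe_photons(
            s, splitter_300, scan_psf_small, optics_small, out_of_range="skip")
        r0, c0 = splitter_300.quadrant_origins_px[3]
        h, w = splitter_300.quadrant_shape_rc
        raw_quadrant = photons[r0:r0 + h, c0:c0 + w]
        r, _ = np.unravel_index(np.argmax(raw_quadrant), raw_quadrant.shape)
        px = optics_small.pixel_size_sample
        expected_row = h - 1 - int(5.0 / px - 0.5)
        assert abs(r - expected_row) <= 1

    def test_empty_scene_zero_read_noise_gives_offset(self, optics_small,
                                                      scan_psf_small,
                                                      splitter_300):
        s = sc.Scene(emitters=[], extent=(32.4, 32.4), thickness=16,
                     background_rate=0.0)
        frame = imager.render_quadframe(s, splitter_300, scan_psf_small,
                                        optics_small,
                                        NoiseModel(read_noise=0.0), seed=0)
        assert np.all(frame.data == 100)

    def test_radiometric_linearity_end_to_end(self, optics_small,
                                              scan_psf_small, splitter_300):
        def frame_for(brightness):
            s = sc.Scene(
                emitters=[sc.Emitter(x=10, y=10, z=2.0, brightness=brightness),
                          sc.Emitter(x=20, y=25, z=9.0, brightness=brightness)],
                extent=(32.4, 32.4), thickness=16.0, background_rate=5.0)
            return imager.render_quadframe_photons(
                s, splitter_300, scan_psf_small, optics_small,
                out_of_range="skip")

        base = frame_for(1000.0)
        scaled = frame_for(3000.0)
        bg = frame_for(0.0)
        np.testing.assert_allclose(scaled - bg, 3.0 * (base - bg),
                                   rtol=1e-6, atol=1e-9)

    def test_quadrant_peak_tracks_plane_center(self, optics_small,
                                               scan_psf_small, splitter_300):
        """A bead swept axially peaks in each quadrant at that plane's center."""
        from multiplane25d._fit import fit_gaussian_1d
        s = single_bead_scene(16.0, 16.0, 0.0, extent=(32.4, 32.4))
        z_scan = np.arange(0.0, 16.01, 0.25)
        peaks = np.zeros((4, z_scan.size))
        for i, z_s in enumerate(z_scan):
            photons = imager.render_quadframe_photons(
                s, splitter_300, scan_psf_small, optics_small, stage_z=z_s,
                out_of_range="skip")
            for p, sub in enumerate(split_quadrants(photons, splitter_300)):
                peaks[p, i] = sub.max()
        for p, center in enumerate(splitter_300.plane_centers):
            sel = np.abs(z_scan - z_scan[np.argmax(peaks[p])]) <= 2.0
            _, mu, _, _ = fit_gaussian_1d(z_scan[sel], peaks[p][sel],
                                          window_fwhm=None)
            assert abs(mu - center) <= 0.3


class TestEdofContrast:
    def test_quadrant_signal_uniform_within_plane_interval(self, optics_small,
                                                           splitter_300):
        """EDOF keeps a bead's quadrant peak within 2.5x of best focus
        anywhere inside the plane's 4 um interval."""
        from multiplane25d import layercake as lc
        from multiplane25d import workflows as wf
        edof = wf.make_scan_psf(optics_small, design=lc.design_layercake(4, 4.0),
                                z_max=3.0, z_step=0.25, crop_halfwidth=3.0)
        peaks = []
        for z in (0.2, 1.0, 2.0, 3.0, 3.8):
            s = single_bead_scene(16.0, 16.0, z, extent=(32.4, 32.4))
            photons = imager.render_quadframe_photons(
                s, splitter_300, edof, optics_small, out_of_range="skip")
            peaks.append(split_quadrants(photons, splitter_300)[0].max())
        assert min(peaks) >= max(peaks) / 2.5


class TestZStack:
    def test_paper_protocol_frame_counts(self, optics_small, focus_psf_small):
        s = sc.make_bead_monolayer(3, extent=(10, 10), z_plane=5.0, seed=0)
        z32 = np.arange(0.0, 16.0, 0.5)
        assert len(z32) == 32
        stack = imager.acquire_zstack(s, z32, focus_psf_small, optics_small,
                                      NoiseModel(), seed=0, shape_px=(64, 64),
                                      out_of_range="skip")
        assert stack.shape == (32, 64, 64)

    def test_64_slice_stack_groups_into_4_aips(self, optics_small,
                                               focus_psf_small):
        from multiplane25d.processing import grouped_aip
        s = sc.make_bead_monolayer(3, extent=(10, 10), z_plane=8.0, seed=1)
        z64 = np.arange(0.0, 16.0, 0.25)
        assert len(z64) == 64
        stack = imager.acquire_zstack(s, z64, focus_psf_small, optics_small,
                                      NoiseModel(), seed=0, shape_px=(48, 48),
                                      out_of_range="skip").astype(float)
        aips = grouped_aip(stack, 16)
        assert aips.shape == (4, 48, 48)
        np.testing.assert_array_equal(aips[1], stack[16:32].mean(axis=0))

    def test_empty_z_list_is_an_error(self, optics_small, focus_psf_small):
        s = sc.make_bead_monolayer(1, extent=(10, 10), seed=0)
        with pytest.raises(ValueError):
            imager.acquire_zstack(s, [], focus_psf_small, optics_small,
                                  NoiseModel(), 0)


class TestGrid:
    def test_paper_grid_has_1020_positions(self):
        plan = imager.plan_grid((2000.0, 2000.0), (93.96, 81.0), 0.3,
                                grid_shape=(30, 34))
        assert len(plan) == 30 * 34 == 1020

    def test_zero_overlap_steps_equal_fov(self):
        plan = imager.plan_grid((300.0, 300.0), (100.0, 100.0), 0.0)
        xs = np.sort(plan.nominal_x.unique())
        np.testing.assert_allclose(np.diff(xs), 100.0)

    def test_tile_larger_than_scene_rejected(self):
        with pytest.raises(ValueError):
            imager.plan_grid((50.0, 50.0), (100.0, 100.0), 0.1)

    def test_overlap_fraction_bounds(self):
        with pytest.raises(ValueError):
            imager.plan_grid((300.0, 300.0), (100.0, 100.0), 0.6)

    def test_serpentine_ordering(self):
        plan = imager.plan_grid((300.0, 300.0), (100.0, 100.0), 0.0)
        row1 = plan[plan.grid_row == 1].sort_values("order")
        assert list(row1.grid_col) == [2, 1, 0]

    def test_channels_share_stage_positions(self, optics_small, focus_psf_small):
        q = 64
        cfg = sp.SplitterConfig(quadrant_shape_px=(q, q),
                                sensor_shape_px=(2 * q, 2 * q))
        px = optics_small.pixel_size_sample
        s = sc.make_two_color_beads(10, (0.0, 0.0), seed=3,
                                    extent=(2 * q * px, 2 * q * px), z_plane=2.0)
        frames, truth = imager.acquire_grid(
            s, cfg, focus_psf_small, optics_small, NoiseModel(), seed=5,
            overlap_fraction=0.1, channels=(0, 1), stage_jitter_px=2.0)
        assert len(frames) == 2 * len(truth)
        for k in range(0, len(frames), 2):
            assert frames[k].metadata["stage_x"] == frames[k + 1].metadata["stage_x"]
            assert frames[k].metadata["stage_y"] == frames[k + 1].metadata["stage_y"]
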