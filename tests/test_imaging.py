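"""Scene generation, rendering, pixel-wise deconvolution and measurement."""

import numpy as np
import pytest

import stainsim as ss
from stainsim.errors import InvalidInputError, NoThresholdError
from scipy import ndimage


class TestCellScene:
    def test_same_seed_reproduces_identical_scene(self):
        a = ss.make_cell_scene(64, 64, 5, seed=42)
        b = ss.make_cell_scene(64, 64, 5, seed=42)
        np.testing.assert_array_equal(a.planes, b.planes)

    def test_single_cell_is_one_connected_region(self):
        scene = ss.make_cell_scene(64, 64, 1, seed=3)
        _, count = ndimage.label(scene.planes.sum(axis=0) > 0,
                                 structure=np.ones((3, 3)))
        assert count == 1

    def test_peak_concentration_respects_range(self):
        scene = ss.make_cell_scene(64, 64, 8, c_range=((0.0, 4.0), (0.0, 2.0)),
                                   seed=1)
        assert scene.planes[0].max() <= 4.0
        assert scene.planes[1].max() <= 2.0
        assert scene.planes.min() >= 0.0

    def test_zero_cells_rejected(self):
        with pytest.raises(InvalidInputError):
            ss.make_cell_scene(64, 64, 0)


class TestSelfSimilarScene:
    def test_single_level_is_flat_squares(self):
        scene = ss.make_selfsimilar_scene(1, [1.0, 2.0], tile_px=16)
        assert set(np.unique(scene.planes[0])) == {1.0, 2.0}
        assert np.all(scene.planes[1] == 0)

    def test_pixel_values_come_from_requested_set(self):
        values = [1.0, 2.0, 4.0]
        scene = ss.make_selfsimilar_scene(2, values, tile_px=20)
        for plane in scene.planes:
            assert set(np.unique(plane)) <= set(values) | {0.0}
        # every requested value appears in both stain planes
        for v in values:
            assert v in scene.planes[0]
            assert v in scene.planes[1]

    def test_contains_pure_first_stain_regions(self):
        scene = ss.make_selfsimilar_scene(2, [1.0, 2.0], tile_px=16)
        pure = (scene.planes[0] > 0) & (scene.planes[1] == 0)
        assert pure.any()

    def test_too_many_levels_rejected(self):
        with pytest.raises(InvalidInputError):
            ss.make_selfsimilar_scene(6, [1.0], tile_px=8)


class TestRenderRgb:
    def test_blank_pixel_quantises_to_white(self, wideband, dab, htx):
        scene = ss.ConcentrationImage(np.zeros((2, 4, 4)), ("DAB", "HTX"))
        rgb = ss.render_rgb(wideband, scene, (dab, htx), quantise=True)
        assert np.all(rgb.data == 255)

    def test_signals_decrease_with_concentration(self, wideband, dab, htx):
        planes = np.zeros((2, 1, 3))
        planes[0, 0] = [0.0, 1.0, 2.0]
        scene = ss.ConcentrationImage(planes, ("DAB", "HTX"))
        rgb = ss.render_rgb(wideband, scene, (dab, htx))
        assert np.all(np.diff(rgb.data, axis=1) < 0)

    def test_single_pixel_matches_direct_forward_call(self, wideband, dab, htx):
        planes = np.array([[[1.3]], [[0.6]]])
        scene = ss.ConcentrationImage(planes, ("DAB", "HTX"))
        rgb = ss.render_rgb(wideband, scene, (dab, htx))
        sample = ss.SampleComposition.of((dab, 1.3), (htx, 0.6))
        for k, ch in enumerate(wideband.channels):
            assert rgb.data[0, 0, k] == pytest.approx(
                ss.channel_signal(wideband, sample, ch), rel=1e-12)

    def test_stain_mismatch_rejected(self, wideband, dab, htx):
        scene = ss.ConcentrationImage(np.zeros((2, 2, 2)), ("HTX", "DAB"))
        with pytest.raises(InvalidInputError):
            ss.render_rgb(wideband, scene, (dab, htx))


def reference_matrix(system, stains):
    return ss.StainMatrix.from_vectors(
        [ss.measure_stain_vector(system, s, 1.0) for s in stains])


class TestDeconvolveImage:
    def test_monochromatic_difference_is_zero(self, mono, dab, htx):
        scene = ss.make_cell_scene(32, 32, 3, seed=9)
        rgb = ss.render_rgb(mono, scene, (dab, htx))
        res = ss.deconvolve_image(rgb, mono, reference_matrix(mono, (dab, htx)),
                                  ground_truth=scene)
        assert np.abs(res.difference.planes).max() < 1e-6

    def test_wideband_contaminates_pure_stain_squares(self, wideband, dab, htx):
        """Nonzero HTX output appears inside pure-DAB squares."""
        scene = ss.make_selfsimilar_scene(2, [1.0, 2.0, 4.0], tile_px=12)
        rgb = ss.render_rgb(wideband, scene, (dab, htx))
        res = ss.deconvolve_image(rgb, wideband,
                                  reference_matrix(wideband, (dab, htx)),
                                  ground_truth=scene)
        pure_dab = (scene.planes[0] > 0) & (scene.planes[1] == 0)
        assert np.abs(res.c_out.planes[1][pure_dab]).max() > 1e-3

    def test_led_error_smaller_than_wideband(self, wideband, led, dab, htx):
        scene = ss.make_selfsimilar_scene(2, [1.0, 2.0, 4.0], tile_px=12)
        errs = {}
        for name, system in (("wb", wideband), ("led", led)):
            rgb = ss.render_rgb(system, scene, (dab, htx))
            res = ss.deconvolve_image(rgb, system,
                                      reference_matrix(system, (dab, htx)),
                                      ground_truth=scene)
            errs[name] = max(res.max_abs_relative_error.values())
        assert errs["led"] < errs["wb"]

    def test_quantised_monochromatic_recovery_within_1_percent(self, mono,
                                                               dab, htx):
        """8-bit rounding keeps monochromatic recovery within 1%.

        Concentrations are kept moderate so the darkest pixel still spans
        enough of the 8-bit range for the half-LSB rounding bound to hold.
        """
        scene = ss.make_selfsimilar_scene(2, [0.25, 0.5], tile_px=10)
        rgb = ss.render_rgb(mono, scene, (dab, htx), quantise=True)
        res = ss.deconvolve_image(rgb, mono, reference_matrix(mono, (dab, htx)),
                                  ground_truth=scene)
        mask = scene.planes.max(axis=0) > 0
        rel = np.abs(res.difference.planes[:, mask]
                     / np.maximum(scene.planes[:, mask], 1e-12))
        assert rel[scene.planes[:, mask] > 0].max() < 0.01

    def test_exact_solver_on_channel_subset(self, mono, dab, htx):
        scene = ss.make_cell_scene(16, 16, 2, seed=4)
        rgb = ss.render_rgb(mono, scene, (dab, htx))
        matrix = reference_matrix(mono, (dab, htx)).project(("B", "G"))
        res = ss.deconvolve_image(rgb, mono, matrix, solver="exact",
                                  ground_truth=scene)
        assert np.abs(res.difference.planes).max() < 1e-9


class TestRescaleTo8Bit:
    def test_endpoints_and_midpoint(self):
        plane = np.array([0.0, 0.5, 1.0])
        out = ss.rescale_to_8bit(plane, 0.0, 1.0)
        np.testing.assert_array_equal(out, [0, 128, 255])

    def test_clipping(self):
        out = ss.rescale_to_8bit(np.array([-1.0, 2.0]), 0.0, 1.0)
        np.testing.assert_array_equal(out, [0, 255])

    def test_invalid_range_rejected(self):
        with pytest.raises(InvalidInputError):
            ss.rescale_to_8bit(np.zeros(3), 1.0, 1.0)


class TestThreshold:
    def test_bimodal_histogram_separated_by_every_method(self):
        plane = np.array([0] * 10 + [255] * 10, dtype=np.uint8).reshape(4, 5)
        for method in ("default", "otsu", "yen"):
            mask = ss.threshold(plane, method)
            np.testing.assert_array_equal(mask, plane == 255)

    def test_otsu_matches_exhaustive_search(self):
        """Otsu equals brute-force maximisation of between-class variance."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            data = np.concatenate([
                rng.integers(0, 80, rng.integers(10, 40)),
                rng.integers(120, 256, rng.integers(10, 40)),
            ]).astype(np.uint8)
            plane = data.reshape(1, -1)
            best_t, best_var = None, -1.0
            for t in range(data.min(), data.max()):
                lo, hi = data[data <= t], data[data > t]
                if lo.size == 0 or hi.size == 0:
                    continue
                var = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
                if var > best_var:
                    best_var, best_t = var, t
            np.testing.assert_array_equal(ss.threshold(plane, "otsu"),
                                          plane > best_t)

    def test_isodata_is_mean_split_fixed_point(self):
        data = np.array([10] * 8 + [40] * 4 + [200] * 6 + [230] * 2,
                        dtype=np.uint8)
        t = float(data.mean())
        for _ in range(100):
            lo, hi = data[data <= t], data[data > t]
            t_new = (lo.mean() + hi.mean()) / 2.0
            if abs(t_new - t) < 0.5:
                break
            t = t_new
        np.testing.assert_array_equal(ss.threshold(data.reshape(2, -1),
                                                   "default"),
                                      data.reshape(2, -1) > t)

    def test_constant_plane_rejected(self):
        with pytest.raises(NoThresholdError):
            ss.threshold(np.full((4, 4), 7, dtype=np.uint8))


class TestLabelAndMeasure:
    def test_two_disjoint_squares(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        plane = np.ones((10, 10)) * 2.0
        meas = ss.label_and_measure(mask, plane)
        assert meas.count == 2
        np.testing.assert_array_equal(meas.areas, [9, 9])
        np.testing.assert_allclose(meas.mean_concentrations, 2.0)
        assert meas.pixel_mean == pytest.approx(2.0)

    def test_diagonal_touching_is_one_object(self):
        mask = np.array([[1, 0], [0, 1]], dtype=bool)
        meas = ss.label_and_measure(mask, np.zeros((2, 2)))
        assert meas.count == 1  # 8-connectivity

    def test_empty_mask(self):
        meas = ss.label_and_measure(np.zeros((5, 5), dtype=bool), np.ones((5, 5)))
        assert meas.count == 0
        assert meas.areas.size == 0

    def test_object_mean_is_pixel_mean(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, :2] = True
        plane = np.arange(9.0).reshape(3, 3)
        meas = ss.label_and_measure(mask, plane)
        assert meas.mean_concentrations[0] == pytest.approx(0.5)


class TestImageIo:
    def test_concentration_tiff_round_trip(self, tmp_path):
        scene = ss.make_cell_scene(16, 16, 2, seed=8)
        path = tmp_path / "scene.tiff"
        scene.to_tiff(path)
        back = ss.ConcentrationImage.from_tiff(path, scene.stain_names)
        np.testing.assert_allclose(back.planes, scene.planes, atol=1e-6)

    def test_quantised_png(self, tmp_path, wideband, dab, htx):
        scene = ss.make_cell_scene(8, 8, 1, seed=2)
        rgb = ss.render_rgb(wideband, scene, (dab, htx), quantise=True)
        rgb.to_png(tmp_path / "img.png")
        assert (tmp_path / "img.png").exists()
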