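"""Preprocessing, segmentation and measurement against constructed and
phantom oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from cytocorr import cytometry as cyto
from cytocorr.io_formats import ImagePlane, ImageStack


def _plane(pixels, px=325.0, channel="DNA"):
    return ImagePlane(np.asarray(pixels, dtype=float), px, channel)


class TestBackgroundSubtraction:
    def test_constant_image_maps_to_zero(self):
        out = cyto.subtract_background(_plane(np.full((64, 64), 37.0)), 10)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-6)

    def test_bright_spot_preserved_background_removed(self):
        img = np.full((128, 128), 20.0)
        img[60:63, 60:63] += 500.0
        out = cyto.subtract_background(_plane(img), 25, downscale=1)
        assert out.pixels[61, 61] == pytest.approx(500.0, rel=0.05)
        far = out.pixels[:30, :30]
        assert np.abs(far).max() < 1.0

    def test_output_is_non_negative_on_random_input(self):
        rng = np.random.default_rng(0)
        out = cyto.subtract_background(_plane(rng.uniform(0, 100, (80, 80))), 15)
        assert out.pixels.min() >= 0

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            cyto.subtract_background(_plane(np.zeros((32, 32))), 40)


class TestFlatfield:
    def test_flatfield_equal_to_plane_gives_constant_mean(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(10, 100, (64, 64))
        out = cyto.flatfield_correct(_plane(img), _plane(img))
        np.testing.assert_allclose(out.pixels, img.mean(), rtol=1e-12)

    def test_constant_flatfield_is_identity(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 50, (32, 32))
        out = cyto.flatfield_correct(_plane(img), np.full((32, 32), 7.0))
        np.testing.assert_allclose(out.pixels, img, rtol=1e-12)

    def test_vignette_round_trip(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(50, 100, (128, 128))
        ii, jj = np.mgrid[0:128, 0:128]
        vignette = 1.0 - 0.4 * (((ii - 64) ** 2 + (jj - 64) ** 2) / 64 ** 2)
        seen = img * vignette
        out = cyto.flatfield_correct(_plane(seen), vignette)
        # mean-normalized flat field restores structure exactly up to the
        # (known) global brightness factor mean(vignette)
        restored = out.pixels / vignette.mean()
        rel = np.abs(restored - img) / img
        assert rel.max() < 0.01

    def test_nonpositive_flatfield_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cyto.flatfield_correct(_plane(np.ones((8, 8))), np.zeros((8, 8)))


class TestSegmentation:
    def test_blank_image_gives_zero_labels(self):
        labels = cyto.segment_nuclei(_plane(np.zeros((64, 64))))
        assert labels.max() == 0

    def test_phantom_with_500_cells_counted_exactly(self, population_500):
        assert len(population_500["cells"]) == len(population_500["truth"])

    def test_overlapping_discs_split_only_with_watershed(self):
        img = np.zeros((100, 100))
        ii, jj = np.mgrid[0:100, 0:100]
        img[(ii - 50) ** 2 + (jj - 38) ** 2 <= 15 ** 2] = 100.0
        img[(ii - 50) ** 2 + (jj - 62) ** 2 <= 15 ** 2] = 100.0
        plane = _plane(img)
        plain = cyto.segment_nuclei(plane, cyto.SegmentationParams(
            threshold=50.0, watershed=False))
        split = cyto.segment_nuclei(plane, cyto.SegmentationParams(
            threshold=50.0, watershed=True, watershed_min_distance_px=10))
        assert plain.max() == 1
        assert split.max() == 2

    def test_border_objects_removed_by_default(self):
        img = np.zeros((60, 60))
        img[0:12, 20:32] = 100.0   # touches the top edge
        img[30:42, 20:32] = 100.0  # interior
        plane = _plane(img)
        p = cyto.SegmentationParams(threshold=50.0, min_area_px=10)
        assert cyto.segment_nuclei(plane, p).max() == 1
        p_keep = cyto.SegmentationParams(threshold=50.0, min_area_px=10,
                                         exclude_border=False)
        assert cyto.segment_nuclei(plane, p_keep).max() == 2


class TestMeasurement:
    def _square_fixture(self, value=7.0):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:20, 10:20] = 1
        img = np.where(labels == 1, value, 0.0)
        stack = ImageStack([_plane(img, px=1000.0, channel="DNA")],
                           channel_names=["DNA"])
        return labels, stack

    def test_uniform_square_measurements(self):
        labels, stack = self._square_fixture()
        cells = cyto.measure_cells(labels, stack)
        assert len(cells) == 1
        row = cells.iloc[0]
        assert row["area_um2"] == pytest.approx(100.0)  # 100 px at 1 um/px
        assert row["mean_DNA"] == pytest.approx(7.0)
        assert row["integrated_DNA"] == pytest.approx(700.0)

    def test_disc_circularity_close_to_one(self):
        ii, jj = np.mgrid[0:64, 0:64]
        labels = (((ii - 32) ** 2 + (jj - 32) ** 2) <= 20 ** 2).astype(np.int32)
        stack = ImageStack([_plane(labels * 10.0)], channel_names=["DNA"])
        cells = cyto.measure_cells(labels, stack)
        assert 0.95 <= cells.iloc[0]["circularity"] <= 1.0

    def test_integrated_intensity_conservation(self, population_500):
        """Sum over cells of integrated DNA equals total DNA within the
        foreground mask (the measurement is additive over labels)."""
        from tests.conftest import ROLLING_BALL_RADIUS, SEG_PARAMS
        stack = population_500["stack"]
        dna = cyto.subtract_background(stack.plane("DNA"), ROLLING_BALL_RADIUS)
        labels = cyto.segment_nuclei(dna, SEG_PARAMS)
        cells = cyto.measure_cells(
            labels, ImageStack([dna], channel_names=["DNA"]))
        total_in_mask = dna.pixels[labels > 0].sum()
        assert cells["integrated_DNA"].sum() == pytest.approx(total_in_mask,
                                                              rel=1e-9)

    def test_split_label_integrals_are_additive(self):
        labels, stack = self._square_fixture()
        whole = cyto.measure_cells(labels, stack)["integrated_DNA"].sum()
        split = labels.copy()
        split[10:20, 15:20] = 2
        parts = cyto.measure_cells(split, stack)["integrated_DNA"].sum()
        assert parts == whole

    def test_permutation_invariance_of_measurements(self):
        labels, stack = self._square_fixture()
        labels2 = labels.copy()
        labels2[25:30, 25:30] = 2
        img = stack.planes[0].pixels.copy()
        img[25:30, 25:30] = 3.0
        stack2 = ImageStack([_plane(img, px=1000.0)], channel_names=["DNA"])
        a = cyto.measure_cells(labels2, stack2)
        swapped = np.where(labels2 == 1, 2, np.where(labels2 == 2, 1, 0))
        b = cyto.measure_cells(swapped.astype(np.int32), stack2)
        a_sorted = a.sort_values("area_px")[["area_px", "mean_DNA"]].to_numpy()
        b_sorted = b.sort_values("area_px")[["area_px", "mean_DNA"]].to_numpy()
        np.testing.assert_allclose(a_sorted, b_sorted)

    def test_shape_mismatch_rejected(self):
        labels, _ = self._square_fixture()
        stack = ImageStack([_plane(np.zeros((16, 16)))], channel_names=["DNA"])
        with pytest.raises(ValueError, match="match"):
            cyto.measure_cells(labels, stack)


class TestSpots:
    def test_phantom_foci_recovered_within_5_percent(self, population_500):
        from tests.conftest import ROLLING_BALL_RADIUS, SEG_PARAMS
        stack = population_500["stack"]
        truth = population_500["truth"]
        foci = cyto.subtract_background(stack.plane("foci"), ROLLING_BALL_RADIUS)
        dna = cyto.subtract_background(stack.plane("DNA"), ROLLING_BALL_RADIUS)
        labels = cyto.segment_nuclei(dna, SEG_PARAMS)
        spots = cyto.detect_spots(foci, labels)
        expected = truth["focus_count"].sum()
        assert abs(len(spots) - expected) / expected <= 0.05

    def test_spot_outside_nuclei_has_parent_zero(self):
        img = np.zeros((64, 64))
        ii, jj = np.mgrid[0:64, 0:64]
        img += 100.0 * np.exp(-((ii - 10.0) ** 2 + (jj - 50.0) ** 2) / 4.0)
        spots = cyto.detect_spots(_plane(img), np.zeros((64, 64), dtype=np.int32))
        assert len(spots) == 1
        assert spots.iloc[0]["parent_cell_id"] == 0

    def test_blank_plane_gives_empty_table(self):
        spots = cyto.detect_spots(_plane(np.zeros((32, 32))),
                                  np.zeros((32, 32), dtype=np.int32))
        assert len(spots) == 0

    def test_large_g1_foci_separable_by_area_and_intensity(self, population_500):
        """The bright large-focus subpopulation separates from ordinary
        foci with both error rates < 5% using an area AND mean-intensity
        gate on the spot table, mapped back to truth-flagged cells."""
        from tests.conftest import ROLLING_BALL_RADIUS, SEG_PARAMS
        stack = population_500["stack"]
        cells = population_500["cells"]
        foci = cyto.subtract_background(stack.plane("foci"), ROLLING_BALL_RADIUS)
        dna = cyto.subtract_background(stack.plane("DNA"), ROLLING_BALL_RADIUS)
        labels = cyto.segment_nuclei(dna, SEG_PARAMS)
        spots = cyto.detect_spots(foci, labels)
        big = spots[(spots["area_px"] > 40) & (spots["mean_intensity"] > 150.0)]
        big_parents = set(big["parent_cell_id"]) - {0}
        true_large = set(cells.loc[cells["large_focus_true"], "cell_id"])
        assert true_large
        missed = len(true_large - big_parents) / len(true_large)
        false = len(big_parents - true_large) / max(len(big_parents), 1)
        assert missed < 0.05
        assert false < 0.05
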