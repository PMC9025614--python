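"""Morphometry: follicle detection, run lengths, scale measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tailmorph as tm
from tailmorph.types import CLASS_CODES

from .conftest import brute_force_longest_run


def blank_image(h=40, w=300, um=1.0):
    return np.zeros((h, w), dtype=np.uint8), um


class TestLongestRun:
    @pytest.mark.parametrize(
        "flags,expected",
        [([], 0), ([False, False], 0), ([True], 1),
         ([True, True, False, True, True, True], 3), ([True] * 7, 7)],
    )
    def test_examples(self, flags, expected):
        assert tm.longest_run(flags) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.booleans(), max_size=60))
    def test_matches_brute_force(self, flags):
        assert tm.longest_run(flags) == brute_force_longest_run(flags)


class TestDetectFollicles:
    def test_intervals_and_centers(self):
        grid, um = blank_image()
        grid[5:10, 10:15] = CLASS_CODES["follicle"]
        grid[5:10, 210:215] = CLASS_CODES["follicle"]
        image = tm.LabelImage(grid=grid, um_per_px=um)
        assert tm.detect_follicles(image) == [(10, 15, 12), (210, 215, 212)]

    def test_no_follicles_is_no_scale(self):
        grid, um = blank_image()
        with pytest.raises(tm.NoScaleError, match="no scale"):
            tm.detect_follicles(tm.LabelImage(grid=grid, um_per_px=um))

    def test_single_follicle_is_no_scale(self):
        grid, um = blank_image()
        grid[5:10, 10:15] = CLASS_CODES["follicle"]
        with pytest.raises(tm.NoScaleError):
            tm.detect_follicles(tm.LabelImage(grid=grid, um_per_px=um))

    def test_roundtrip_against_generator_placement(self):
        img, truth = tm.generate_label_image(500, 40.0, [25] * 5, 1.0, seed=4)
        follicles = tm.detect_follicles(img)
        assert len(follicles) == 2
        assert [f[2] for f in follicles] == truth["follicle_centers_px"]


class TestMeasureScale:
    def _image_with_runs(self, runs, w=260, um=1.0):
        """Two follicles at the ends; granular runs given as (start, length)."""
        grid, _ = blank_image(w=w, um=um)
        grid[10:30, 0:5] = CLASS_CODES["follicle"]
        grid[10:30, w - 5: w] = CLASS_CODES["follicle"]
        grid[20:28, 5: w - 5] = CLASS_CODES["epidermis"]
        for start, length in runs:
            grid[18:20, start: start + length] = CLASS_CODES["granular"]
        image = tm.LabelImage(grid=grid, um_per_px=um)
        window = tm.scale_windows(tm.detect_follicles(image))[0]
        return image, window

    def test_longest_run_among_fragments(self):
        image, window = self._image_with_runs([(10, 30), (60, 80), (160, 15)])
        rec = tm.measure_scale(image, window)
        assert rec.A_um == 80.0

    def test_sum_mode_totals_coverage(self):
        image, window = self._image_with_runs([(10, 30), (60, 80), (160, 15)])
        rec = tm.measure_scale(image, window, run_mode="sum")
        assert rec.A_um == 125.0

    def test_full_coverage_a_equals_b(self):
        image, window = self._image_with_runs([(0, 260)])
        rec = tm.measure_scale(image, window)
        assert rec.A_um == rec.B_um

    def test_thickness_is_epidermis_pixel_count(self):
        image, window = self._image_with_runs([])
        rec = tm.measure_scale(image, window)
        assert rec.thickness_um == (8.0,) * 5

    def test_invalid_thickness_columns_are_excluded(self, caplog):
        image, window = self._image_with_runs([])
        # erase the epidermis at the first sampled column
        col = window.left_px + int(np.floor(1 / 6 * (window.right_px - window.left_px)))
        image.grid[:, col] = 0
        with caplog.at_level("WARNING"):
            rec = tm.measure_scale(image, window)
        assert len(rec.thickness_um) == 4
        assert "excluded" in caplog.text

    def test_translation_invariance(self):
        image, window = self._image_with_runs([(60, 80)], w=260)
        rec = tm.measure_scale(image, window)
        k = 17
        shifted = np.zeros((image.grid.shape[0], image.grid.shape[1] + k), dtype=np.uint8)
        shifted[:, k:] = image.grid
        image2 = tm.LabelImage(grid=shifted, um_per_px=image.um_per_px)
        window2 = tm.scale_windows(tm.detect_follicles(image2))[0]
        rec2 = tm.measure_scale(image2, window2)
        assert (rec2.A_um, rec2.B_um, rec2.thickness_um) == (rec.A_um, rec.B_um, rec.thickness_um)


class TestRoundTrip:
    @pytest.mark.parametrize("degree", [0.0, 25.0, 50.0, 75.0, 100.0])
    @pytest.mark.parametrize("um", [1.0, 2.0])
    def test_degree_and_thickness_recovered(self, degree, um):
        B = 420.0
        thickness = [24.0, 30.0, 27.0, 33.0, 29.0]
        img, truth = tm.generate_label_image(B, degree, thickness, um, seed=13)
        rec = tm.measure_image(img)[0]
        tol_pp = 100.0 * 2 * um / B
        assert rec.degree == pytest.approx(truth["degree"], abs=tol_pp)
        for got, want in zip(rec.thickness_um, truth["thickness_um"]):
            assert abs(got - want) <= um


class TestBatchIO:
    def test_write_measure_directory(self, tmp_path):
        for i, deg in enumerate([20.0, 60.0]):
            img, truth = tm.generate_label_image(400, deg, [28] * 5, 2.0, seed=i)
            truth.update(group="g", animal=1, scale=i)
            tm.write_label_image(img, truth, tmp_path / f"scale_{i}.tif")
        frame = tm.measure_directory(tmp_path)
        assert len(frame) == 2
        degrees = 100 * frame["A_um"] / frame["B_um"]
        assert degrees.round(0).tolist() == [20.0, 60.0]

    def test_empty_directory_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="no images found"):
            tm.measure_directory(tmp_path)
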