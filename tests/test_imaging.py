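"""Segmentation thresholds, measurement arithmetic and truth recovery."""

import numpy as np
import pandas as pd
import pytest

from phasefit import (
    SegmentationParams,
    classify_foci_size,
    measure_cells,
    render_synthetic_image,
    segment_cells,
    segment_foci,
)
from phasefit.imaging import analyze_image, match_labels

# 0.2 um/px -> 0.04 um^2 per pixel
PARAMS = SegmentationParams(pixel_scale=0.2)


def frame(h=80, w=80):
    return np.zeros((h, w), dtype=np.uint8)


def put_rect(img, r0, c0, h, w, value):
    img[r0:r0 + h, c0:c0 + w] = value
    return img


class TestCellThresholdSemantics:
    def test_intensity_20_included_19_excluded(self):
        # 30x40 px = 48 um^2, inside the area window
        ok = put_rect(frame(), 10, 10, 30, 40, 20)
        mask, regions = segment_cells(ok, PARAMS)
        assert len(regions) == 1
        dim = put_rect(frame(), 10, 10, 30, 40, 19)
        _, none = segment_cells(dim, PARAMS)
        assert len(none) == 0

    def test_area_bounds_inclusive(self):
        # 25x50 px = exactly 50 um^2: included (closed interval)
        at_max = put_rect(frame(), 10, 10, 25, 50, 30)
        _, r = segment_cells(at_max, PARAMS)
        assert len(r) == 1 and r["area_um2"].iloc[0] == pytest.approx(50.0)
        # 10x20 px = exactly 8 um^2: included
        at_min = put_rect(frame(), 10, 10, 10, 20, 30)
        _, r = segment_cells(at_min, PARAMS)
        assert len(r) == 1 and r["area_um2"].iloc[0] == pytest.approx(8.0)

    def test_oversized_region_excluded(self):
        # 30x50 px = 60 um^2 exceeds the 50 um^2 upper bound
        big = put_rect(frame(), 10, 10, 30, 50, 30)
        _, r = segment_cells(big, PARAMS)
        assert len(r) == 0

    def test_low_circularity_excluded(self):
        # a 3x100-px filament is 12 um^2 (in range) but far from circular
        line = put_rect(frame(20, 120), 8, 5, 3, 100, 30)
        _, r = segment_cells(line, PARAMS)
        assert len(r) == 0

    def test_border_touching_excluded(self):
        img = put_rect(frame(), 0, 10, 30, 40, 30)
        _, r = segment_cells(img, PARAMS)
        assert len(r) == 0

    def test_blank_image(self):
        mask, r = segment_cells(frame(), PARAMS)
        assert mask.max() == 0 and len(r) == 0


class TestFociThresholdSemantics:
    def _cell_with_focus(self, focus_value, focus_h=10, focus_w=25):
        img = put_rect(frame(), 10, 10, 30, 40, 25)
        put_rect(img, 20, 15, focus_h, focus_w, focus_value)
        return img

    def test_intensity_40_included_39_excluded(self):
        img = self._cell_with_focus(40)
        cm, _ = segment_cells(img, PARAMS)
        fm, foci = segment_foci(img, cm, PARAMS)
        assert len(foci) == 1
        img2 = self._cell_with_focus(39)
        cm2, _ = segment_cells(img2, PARAMS)
        _, none = segment_foci(img2, cm2, PARAMS)
        assert len(none) == 0

    def test_focus_area_10_um2_included_15_excluded(self):
        # 10x25 px = exactly 10 um^2
        img = self._cell_with_focus(60, focus_h=10, focus_w=25)
        cm, _ = segment_cells(img, PARAMS)
        _, foci = segment_foci(img, cm, PARAMS)
        assert len(foci) == 1 and foci["area_um2"].iloc[0] == pytest.approx(10.0)
        # 15x25 px = 15 um^2 exceeds the bound
        img2 = self._cell_with_focus(60, focus_h=15, focus_w=25)
        cm2, _ = segment_cells(img2, PARAMS)
        _, none = segment_foci(img2, cm2, PARAMS)
        assert len(none) == 0

    def test_focus_outside_cells_discarded(self):
        img = frame()
        put_rect(img, 60, 60, 5, 10, 60)  # bright blob, no cell (too small for one)
        cm = np.zeros_like(img, dtype=np.int32)
        _, foci = segment_foci(img, cm, PARAMS)
        assert len(foci) == 0


class TestMeasurement:
    def test_integrated_intensity_partition(self):
        # 1200-px cell at 25 a.u. with a 250-px focus at 40 a.u.
        img = put_rect(frame(), 10, 10, 30, 40, 25)
        put_rect(img, 20, 15, 10, 25, 40)
        cm, _ = segment_cells(img, PARAMS)
        fm, _ = segment_foci(img, cm, PARAMS)
        rec = measure_cells(img, cm, fm, strain="AGG", pixel_scale=0.2).iloc[0]
        assert rec["f_total"] == 950 * 25 + 250 * 40
        assert rec["f_foci"] == 250 * 40
        assert rec["f_cyto"] == 950 * 25
        assert rec["n_foci"] == 1
        assert rec["area_um2"] == pytest.approx(48.0)

    def test_cell_without_foci(self):
        img = put_rect(frame(), 10, 10, 30, 40, 25)
        cm, _ = segment_cells(img, PARAMS)
        fm = np.zeros_like(cm)
        rec = measure_cells(img, cm, fm, pixel_scale=0.2).iloc[0]
        assert rec["f_cyto"] == rec["f_total"]


class TestFociClassification:
    def test_no_foci_is_small(self):
        assert classify_foci_size(0.0, 100.0) == "SMALL"

    def test_exactly_70_percent_is_big(self):
        assert classify_foci_size(70.0, 100.0) == "BIG"

    def test_just_below_is_small(self):
        assert classify_foci_size(69.0, 100.0) == "SMALL"

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            classify_foci_size(0.0, 0.0)


class TestGroundTruthRecovery:
    def test_counts_and_assignment_match_truth(self, clean_image, seg_params):
        cm, regions = segment_cells(clean_image, seg_params)
        fm, foci = segment_foci(clean_image.pixels, cm, seg_params)
        assert cm.max() == clean_image.truth_cells.max() == len(regions)
        assert fm.max() == clean_image.truth_foci.max() == len(foci)
        cell_map = match_labels(cm, clean_image.truth_cells)
        focus_map = match_labels(fm, clean_image.truth_foci)
        assert all(v > 0 for v in cell_map.values())
        assert all(v > 0 for v in focus_map.values())
        # parent assignment: the detected parent maps to the truth parent
        truth_parent = {}
        for fid in range(1, clean_image.truth_foci.max() + 1):
            owners = clean_image.truth_cells[clean_image.truth_foci == fid]
            truth_parent[fid] = int(owners.max())
        for _, row in foci.iterrows():
            assert cell_map[int(row["cell_id"])] == truth_parent[focus_map[int(row["focus_id"])]]

    def test_integrated_intensity_within_one_percent(self, clean_image, seg_params):
        cells = analyze_image(clean_image, seg_params)
        cm, _ = segment_cells(clean_image, seg_params)
        cell_map = match_labels(cm, clean_image.truth_cells)
        truth = clean_image.truth_table.set_index("cell_id")
        for _, row in cells.iterrows():
            t = truth.loc[cell_map[int(row["cell_id"])]]
            assert abs(row["f_total"] - t["f_total"]) <= 0.01 * t["f_total"]
            assert row["n_foci"] == t["n_foci"]

    def test_conservation_every_record(self, clean_image, seg_params):
        cells = analyze_image(clean_image, seg_params)
        assert np.array_equal(cells["f_total"].to_numpy(),
                              (cells["f_foci"] + cells["f_cyto"]).to_numpy())

    def test_robust_to_background_noise(self, agg_cells):
        cells = agg_cells.head(100).copy()
        cells["area_um2"] = np.clip(cells["area_um2"], 10.0, 45.0)
        noisy = render_synthetic_image(cells, background_sd=5.0, seed=33)
        params = SegmentationParams(pixel_scale=noisy.pixel_scale)
        cm, regions = segment_cells(noisy, params)
        matched = {v for v in match_labels(cm, noisy.truth_cells).values() if v > 0}
        n_truth = noisy.truth_cells.max()
        recall = len(matched) / n_truth
        precision = len(matched) / max(1, len(regions))
        assert recall >= 0.95 and precision >= 0.95
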