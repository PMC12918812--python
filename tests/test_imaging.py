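"""Segmentation and morphometrics against constructed and synthetic truth."""

import numpy as np
import pandas as pd
import pytest

from condensatekit import imaging, synthdata

from _oracles import max_project_loop


def _disc_image(shape, discs, base=0.0):
    """discs: list of (row, col, radius, value)."""
    img = np.full(shape, float(base))
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for r, c, rad, v in discs:
        img[(yy - r) ** 2 + (xx - c) ** 2 <= rad**2] = v
    return img


class TestMaxProject:
    def test_single_plane_identity(self, rng):
        plane = rng.random((8, 8))
        np.testing.assert_array_equal(imaging.max_project(plane[None]), plane)

    def test_doubled_plane(self, rng):
        a = rng.random((6, 6))
        np.testing.assert_array_equal(imaging.max_project(np.stack([a, 2 * a])), 2 * a)

    def test_matches_loop_oracle(self, rng):
        stack = rng.random((5, 12, 9))
        np.testing.assert_allclose(imaging.max_project(stack), max_project_loop(stack))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            imaging.max_project(np.empty((0, 4, 4)))


class TestSegment:
    def test_blank_image_yields_no_objects(self):
        labels = imaging.segment(np.zeros((64, 64)), "nuclei")
        assert labels.max() == 0

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="unknown backend"):
            imaging.segment(np.zeros((8, 8)), "nuclei", backend="nonesuch")

    def test_custom_backend_registry(self):
        imaging.register_backend("everything", "nuclei",
                                 lambda img, **kw: np.ones(img.shape, dtype=int))
        labels = imaging.segment(np.zeros((4, 4)), "nuclei", backend="everything")
        assert (labels == 1).all()

    def test_condensate_recovery_iou(self, small_scene):
        """Default backend recovers >= 90% of truth condensates at IoU >= 0.5."""
        image, truth = small_scene
        nuclei = imaging.segment(image[0], "nuclei")
        cond = imaging.segment(image[0], "condensates", nuclei=nuclei)
        recovered = 0
        for cid in truth.condensates["condensate_id"]:
            tmask = truth.condensate_labels == cid
            overlap_labels, counts = np.unique(cond[tmask][cond[tmask] > 0],
                                               return_counts=True)
            best = 0.0
            for lab, inter in zip(overlap_labels, counts):
                union = tmask.sum() + (cond == lab).sum() - inter
                best = max(best, inter / union)
            recovered += best >= 0.5
        assert recovered >= 0.9 * len(truth.condensates)

    def test_touching_nuclei_split_by_watershed(self):
        img = _disc_image((90, 150), [(45, 50, 22, 200.0), (45, 92, 22, 200.0)], base=10.0)
        rng = np.random.default_rng(0)
        img = img + rng.normal(0, 3, img.shape)
        labels = imaging.segment(img, "nuclei")
        assert labels.max() == 2

    def test_all_background_condensates_valid(self):
        nuclei = np.zeros((32, 32), dtype=int)
        nuclei[8:24, 8:24] = 1
        img = np.full((32, 32), 100.0)
        labels = imaging.segment(img, "condensates", nuclei=nuclei)
        assert labels.max() == 0


class TestStandardizeCrop:
    def test_shape_and_central_placement(self):
        img = np.zeros((300, 300))
        mask = np.zeros((300, 300), dtype=bool)
        mask[100:200, 120:200] = True   # 100 x 80 box
        img[mask] = 7.0
        out = imaging.standardize_nucleus_crop(img, mask)
        assert out.shape == (512, 512)
        assert out[256, 256] == pytest.approx(7.0)
        assert out[10, 10] == 0.0

    def test_all_zero_crop(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:30, 10:30] = True
        out = imaging.standardize_nucleus_crop(np.zeros((50, 50)), mask)
        assert out.shape == (512, 512) and not out.any()

    def test_oversized_box_downscaled_with_warning(self):
        mask = np.zeros((600, 600), dtype=bool)
        mask[10:500, 10:400] = True
        with pytest.warns(UserWarning, match="downscaling"):
            out = imaging.standardize_nucleus_crop(np.ones((600, 600)), mask)
        assert out.shape == (512, 512)


class TestCondensateTable:
    def _simple_scene(self, discs, shape=(64, 64), value=300.0):
        nuclei = np.zeros(shape, dtype=int)
        nuclei[2:-2, 2:-2] = 1
        cond = np.zeros(shape, dtype=int)
        img = np.full(shape, 100.0)
        for i, mask in enumerate(discs, start=1):
            cond[mask] = i
            img[mask] = value
        return img, nuclei, cond

    def test_disc_eccentricity_near_zero(self):
        yy, xx = np.mgrid[:64, :64]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 10**2
        img, nuclei, cond = self._simple_scene([disc])
        table = imaging.condensate_table(img, nuclei, cond)
        assert table.loc[0, "eccentricity"] < 0.1

    def test_line_eccentricity_near_one(self):
        line = np.zeros((64, 64), dtype=bool)
        line[32, 20:29] = True  # 1 x 9 segment
        img, nuclei, cond = self._simple_scene([line])
        table = imaging.condensate_table(img, nuclei, cond)
        assert table.loc[0, "eccentricity"] > 0.95

    def test_uniform_intensity_sums(self):
        blob = np.zeros((64, 64), dtype=bool)
        blob[10:15, 10:15] = True  # 25 px
        img, nuclei, cond = self._simple_scene([blob], value=7.0)
        table = imaging.condensate_table(img, nuclei, cond)
        assert table.loc[0, "total_intensity"] == pytest.approx(25 * 7.0)
        assert table.loc[0, "mean_intensity"] == pytest.approx(7.0)

    def test_condensate_outside_nuclei_dropped_and_counted(self):
        nuclei = np.zeros((32, 32), dtype=int)
        nuclei[4:16, 4:16] = 1
        cond = np.zeros((32, 32), dtype=int)
        cond[20:24, 20:24] = 1  # fully outside
        cond[6:9, 6:9] = 2
        table = imaging.condensate_table(np.ones((32, 32)), nuclei, cond)
        assert len(table) == 1
        assert table.attrs["n_dropped_outside"] == 1

    def test_eccentricity_invariant_to_rotation_and_scaling(self, small_scene):
        image, truth = small_scene
        t1 = imaging.condensate_table(image[0], truth.nucleus_labels,
                                      truth.condensate_labels)
        t2 = imaging.condensate_table(np.rot90(image[0]) * 3.7,
                                      np.rot90(truth.nucleus_labels),
                                      np.rot90(truth.condensate_labels))
        e1 = t1.sort_values("condensate_id")["eccentricity"].to_numpy()
        e2 = t2.sort_values("condensate_id")["eccentricity"].to_numpy()
        np.testing.assert_allclose(e1, e2, atol=1e-9)


class TestNucleusMetrics:
    def test_uniform_nucleus_partition_is_one(self):
        nuclei = np.zeros((40, 40), dtype=int)
        nuclei[5:35, 5:35] = 1
        cond = np.zeros((40, 40), dtype=int)
        cond[10:15, 10:15] = 1
        img = np.full((40, 40), 50.0)
        metrics = imaging.nucleus_metrics(img, nuclei, cond)
        assert metrics.loc[0, "apparent_partition"] == pytest.approx(1.0)

    def test_no_foci_convention(self):
        nuclei = np.zeros((20, 20), dtype=int)
        nuclei[2:18, 2:18] = 1
        metrics = imaging.nucleus_metrics(np.ones((20, 20)), nuclei,
                                          np.zeros((20, 20), dtype=int))
        row = metrics.iloc[0]
        assert row["n_foci"] == 0 and row["apparent_partition"] == 1.0
        assert row["no_foci"] and np.isnan(row["mean_foci_area"])

    def test_truth_mask_partition_within_5pct(self, small_scene):
        image, truth = small_scene
        table = imaging.condensate_table(image[0], truth.nucleus_labels,
                                         truth.condensate_labels)
        metrics = imaging.nucleus_metrics(image[0], truth.nucleus_labels,
                                          truth.condensate_labels, table)
        with_foci = metrics[metrics["n_foci"] > 0]
        assert with_foci["apparent_partition"].mean() == pytest.approx(3.0, rel=0.05)

    def test_foci_counts_sum_to_record_count(self, small_scene):
        image, truth = small_scene
        table = imaging.condensate_table(image[0], truth.nucleus_labels,
                                         truth.condensate_labels)
        metrics = imaging.nucleus_metrics(image[0], truth.nucleus_labels,
                                          truth.condensate_labels, table)
        assert metrics["n_foci"].sum() == len(table)
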