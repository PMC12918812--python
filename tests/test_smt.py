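"""Track linking, filtering, ROI assignment, MSD and diffusion estimation."""

import numpy as np
import pandas as pd
import pytest

from condensatekit import smt, synthdata

from _oracles import msd_double_loop


def _detections(tracks_xy, dt=0.03):
    """tracks_xy: list of (n, 2) position arrays, one per molecule."""
    rows = []
    for xy in tracks_xy:
        for frame, (x, y) in enumerate(xy):
            rows.append({"frame": frame, "x": x, "y": y})
    det = pd.DataFrame(rows)
    det.attrs["dt"] = dt
    return det


class TestLinking:
    def test_single_molecule_full_length_track(self):
        xy = np.cumsum(np.full((30, 2), 0.5), axis=0)
        linked = smt.link_detections(_detections([xy]), max_disp=2.0)
        assert linked["track_id"].nunique() == 1
        assert len(linked) == 30

    def test_two_distant_molecules_stay_separate(self):
        truth = synthdata.TrackTruth(D_true=0.05, n_tracks=1, track_length=40)
        a = synthdata.gen_tracks(truth, seed=1)[["x", "y"]].to_numpy()
        b = a + 30.0  # always > 20 units away
        linked = smt.link_detections(_detections([a, b]), max_disp=5.0)
        assert linked["track_id"].nunique() == 2
        for _, g in linked.groupby("track_id"):
            assert len(g) == 40

    def test_permutation_invariance_within_frames(self, rng):
        truth = synthdata.TrackTruth(D_true=0.2, n_tracks=6, track_length=20,
                                     box=(0, 30, 0, 30))
        det = synthdata.gen_tracks(truth, seed=3)[["frame", "x", "y"]]
        shuffled = det.sample(frac=1.0, random_state=0)
        a = smt.link_detections(det, max_disp=2.0)
        b = smt.link_detections(shuffled, max_disp=2.0)
        pd.testing.assert_frame_equal(a, b)

    def test_displacement_beyond_max_breaks_track(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [20.0, 0.0], [21.0, 0.0]])
        linked = smt.link_detections(_detections([xy]), max_disp=5.0)
        assert linked["track_id"].nunique() == 2

    def test_duplicate_detections_deduplicated_with_warning(self):
        det = pd.DataFrame({"frame": [0, 0, 1], "x": [1.0, 1.0, 1.2],
                            "y": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="duplicate"):
            linked = smt.link_detections(det, max_disp=5.0)
        assert (linked["frame"] == 0).sum() == 1

    def test_greedy_and_lap_agree_when_sparse(self):
        truth = synthdata.TrackTruth(D_true=0.1, n_tracks=8, track_length=25,
                                     box=(0, 40, 0, 40))
        det = synthdata.gen_tracks(truth, seed=9)[["frame", "x", "y"]]
        a = smt.link_detections(det, max_disp=2.0, method="greedy")
        b = smt.link_detections(det, max_disp=2.0, method="lap")
        pd.testing.assert_frame_equal(a, b)


class TestFilterTracks:
    def test_strictly_longer_than_min_frames(self):
        rows = []
        for tid, n in enumerate([14, 15, 16]):
            for f in range(n):
                rows.append({"track_id": tid, "frame": f, "x": 0.0, "y": 0.0})
        tracks = pd.DataFrame(rows)
        kept = smt.filter_tracks(tracks, min_frames=15)
        assert kept["track_id"].unique().tolist() == [2]

    def test_min_zero_keeps_everything(self):
        tracks = pd.DataFrame({"track_id": [0, 0, 1], "frame": [0, 1, 0],
                               "x": [0.0] * 3, "y": [0.0] * 3})
        assert len(smt.filter_tracks(tracks, min_frames=0)) == 3


class TestAssignTracks:
    def _track(self, xs, tid=0):
        return pd.DataFrame({"track_id": tid, "frame": range(len(xs)),
                             "x": xs, "y": [1.0] * len(xs)})

    def test_fully_inside_assigned(self):
        out = smt.assign_tracks(self._track([1.0, 1.2, 1.4]), [(0, 2, 0, 2)])
        assert out.loc[0, "roi"] == 0

    def test_fully_outside_pooled(self):
        out = smt.assign_tracks(self._track([5.0, 5.2]), [(0, 2, 0, 2)])
        assert out.loc[0, "roi"] == -1

    def test_boundary_straddling_threshold(self):
        xs = [1.0, 1.0, 1.0, 5.0, 5.0]  # 60% inside
        track = self._track(xs)
        assert smt.assign_tracks(track, [(0, 2, 0, 2)]).loc[0, "roi"] == 0
        assert smt.assign_tracks(track, [(0, 2, 0, 2)],
                                 min_fraction=0.7).loc[0, "roi"] == -1

    def test_overlapping_rois_majority_wins(self):
        xs = [1.0, 1.0, 1.0, 3.0, 3.0]
        out = smt.assign_tracks(self._track(xs), [(0, 2, 0, 2), (0, 4, 0, 4)])
        assert out.loc[0, "roi"] == 1


class TestMsdAndDiffusion:
    def test_stationary_track(self):
        track = pd.DataFrame({"track_id": 0, "frame": range(10),
                              "x": [2.0] * 10, "y": [3.0] * 10})
        curve = smt.msd(track, dt=0.03)
        assert (curve.values == 0).all()
        assert smt.estimate_D(curve).D == 0.0

    def test_deterministic_straight_line(self):
        step = 0.1  # µm per frame
        track = pd.DataFrame({"track_id": 0, "frame": range(20),
                              "x": np.arange(20) * step, "y": np.zeros(20)})
        curve = smt.msd(track, dt=0.03)
        k = np.arange(1, 20)
        np.testing.assert_allclose(curve.values, (step * k) ** 2)

    def test_matches_double_loop_oracle_exactly(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            xy = rng.normal(0, 1, size=(n, 2)).cumsum(axis=0)
            track = pd.DataFrame({"track_id": 0, "frame": range(n),
                                  "x": xy[:, 0], "y": xy[:, 1]})
            # vectorized and scalar accumulation differ only in the last ulp
            np.testing.assert_allclose(smt.msd(track, dt=0.03).values,
                                       msd_double_loop(xy), rtol=1e-13)

    def test_too_short_track_rejected(self):
        track = pd.DataFrame({"track_id": 0, "frame": [0], "x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError):
            smt.msd(track)

    def test_recovers_planted_diffusion_coefficient(self):
        tracks = synthdata.gen_tracks(
            synthdata.TrackTruth(D_true=0.5, n_tracks=200, track_length=100), seed=7)
        est = smt.estimate_D_per_track(tracks, dt=0.03)
        assert est["D"].median() == pytest.approx(0.5, rel=0.1)

    def test_negative_slope_clipped_and_flagged(self):
        # anti-correlated jitter: MSD decreases with lag -> negative slope
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.05, 0.95, 0.1, 0.9])
        track = pd.DataFrame({"track_id": 0, "frame": range(10), "x": x,
                              "y": np.zeros(10)})
        curve = smt.msd(track, dt=0.03)
        est = smt.estimate_D(curve, fit_lags=8)
        assert est.D >= 0.0
        if est.clipped:
            assert est.D == 0.0


class TestCondensateBoundary:
    def test_single_blob_one_roi(self):
        yy, xx = np.mgrid[:60, :60]
        img = 100 + 500 * np.exp(-((yy - 30) ** 2 + (xx - 30) ** 2) / 50)
        rois = smt.trace_condensate_boundary(img)
        assert len(rois) == 1
        r0, c0, r1, c1 = rois[0]
        assert r0 <= 30 < r1 and c0 <= 30 < c1

    def test_two_blobs_split_at_valley(self):
        yy, xx = np.mgrid[:60, :100]
        img = (100 + 500 * np.exp(-((yy - 30) ** 2 + (xx - 30) ** 2) / 40)
               + 500 * np.exp(-((yy - 30) ** 2 + (xx - 70) ** 2) / 40))
        rois = smt.trace_condensate_boundary(img)
        assert len(rois) == 2

    def test_blank_image_empty(self):
        assert smt.trace_condensate_boundary(np.zeros((30, 30))) == []
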