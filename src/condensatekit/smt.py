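"""Single-molecule tracking: linking, condensate ROIs, MSD and diffusion fits.

Detections are linked frame-to-frame with a greedy mutual-nearest-neighbour
assignment (links above ``max_disp`` rejected, no gap closing — a track ends
the first frame it is unmatched); a full linear-assignment solve is
available with ``method="lap"``.  Tracks are filtered to those *longer than*
``min_frames`` (strict inequality), assigned to condensate bounding-box
ROIs by majority of localizations, and each surviving track yields a
time-averaged mean-squared-displacement curve and a diffusion coefficient
from the 2D Brownian relation MSD = 4·D·t, fitted by least squares through
the origin over the first ``fit_lags`` lags (default 1–4, the standard
low-bias range).  Negative fitted slopes are clipped to D = 0 and flagged.

Coordinates are column ``x``/``y`` in µm (or px with a recorded pixel size
conversion applied upstream); the frame interval ``dt`` defaults to 0.03 s
(30 ms/frame).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters, measure, segmentation

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "link_detections",
    "filter_tracks",
    "assign_tracks",
    "msd",
    "estimate_D",
    "estimate_D_per_track",
    "trace_condensate_boundary",
]

DEFAULT_DT = 0.03  # s/frame


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track: msd(k·dt) over lags 1..L."""

    lags: np.ndarray    # seconds
    values: np.ndarray  # µm² (or px² if the track was not converted)
    track_id: int | None = None


@dataclass
class DiffusionEstimate:
    D: float            # µm²/s, >= 0
    fit_lags: int
    track_id: int | None = None
    clipped: bool = False  # True when a negative slope was clipped to 0


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _dedupe(frame_df: pd.DataFrame) -> pd.DataFrame:
    dup = frame_df.duplicated(subset=["x", "y"])
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate detections in one frame; deduplicated")
        frame_df = frame_df[~dup]
    return frame_df


def _pair_frames(prev_xy: np.ndarray, cur_xy: np.ndarray, max_disp: float,
                 method: str) -> list[tuple[int, int]]:
    """Match previous to current detections; returns (prev_idx, cur_idx) pairs."""
    if len(prev_xy) == 0 or len(cur_xy) == 0:
        return []
    d = np.sqrt(((prev_xy[:, None, :] - cur_xy[None, :, :]) ** 2).sum(-1))
    if method == "lap":
        from scipy.optimize import linear_sum_assignment

        cost = np.where(d <= max_disp, d**2, 1e12)
        rows, cols = linear_sum_assignment(cost)
        return [(int(r), int(c)) for r, c in zip(rows, cols) if d[r, c] <= max_disp]
    # greedy: repeatedly take the globally closest admissible pair, which is
    # by construction mutual-nearest among the remaining detections
    pairs = []
    d = d.copy()
    d[d > max_disp] = np.inf
    while np.isfinite(d).any():
        r, c = np.unravel_index(np.argmin(d), d.shape)
        pairs.append((int(r), int(c)))
        d[r, :] = np.inf
        d[:, c] = np.inf
    return pairs


def link_detections(detections: pd.DataFrame, max_disp: float = 5.0,
                    method: str = "greedy") -> pd.DataFrame:
    """Link per-frame detections (columns frame, x, y) into tracks.

    Frame-to-frame assignment minimizes displacement; links longer than
    ``max_disp`` are rejected and there is no gap closing, so a detection
    unmatched in the next frame terminates its track.  Detections are
    canonically sorted within each frame, making the result invariant to
    input row order.  Returns a (track_id, frame, x, y) table; ``attrs``
    are propagated.
    """
    if method not in ("greedy", "lap"):
        raise ValueError("method must be 'greedy' or 'lap'")
    det = detections.sort_values(["frame", "x", "y"], kind="mergesort").reset_index(drop=True)
    out_rows: list[dict] = []
    next_track = 0
    open_tracks: dict[int, tuple[float, float]] = {}  # track_id -> last (x, y)
    prev_frame: int | None = None

    for frame, group in det.groupby("frame", sort=True):
        group = _dedupe(group)
        cur_xy = group[["x", "y"]].to_numpy(dtype=float)
        if prev_frame is not None and frame == prev_frame + 1 and open_tracks:
            ids = list(open_tracks)
            prev_xy = np.array([open_tracks[t] for t in ids])
            pairs = _pair_frames(prev_xy, cur_xy, max_disp, method)
        else:
            pairs = []  # gap in frames: all open tracks end
        matched_cur = set()
        new_open: dict[int, tuple[float, float]] = {}
        for r, c in pairs:
            tid = ids[r]
            new_open[tid] = (cur_xy[c, 0], cur_xy[c, 1])
            out_rows.append({"track_id": tid, "frame": int(frame),
                             "x": cur_xy[c, 0], "y": cur_xy[c, 1]})
            matched_cur.add(c)
        for c in range(len(cur_xy)):
            if c not in matched_cur:
                tid = next_track
                next_track += 1
                new_open[tid] = (cur_xy[c, 0], cur_xy[c, 1])
                out_rows.append({"track_id": tid, "frame": int(frame),
                                 "x": cur_xy[c, 0], "y": cur_xy[c, 1]})
        open_tracks = new_open
        prev_frame = int(frame)

    tracks = pd.DataFrame(out_rows, columns=["track_id", "frame", "x", "y"])
    tracks = tracks.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
    tracks.attrs.update(detections.attrs)
    return tracks


def filter_tracks(tracks: pd.DataFrame, min_frames: int = 15) -> pd.DataFrame:
    """Keep tracks strictly longer than ``min_frames`` localizations."""
    lengths = tracks.groupby("track_id")["frame"].size()
    keep = lengths.index[lengths > min_frames]
    out = tracks[tracks["track_id"].isin(keep)].reset_index(drop=True)
    out.attrs.update(tracks.attrs)
    return out


def assign_tracks(tracks: pd.DataFrame, rois: list[tuple[float, float, float, float]],
                  min_fraction: float = 0.5) -> pd.DataFrame:
    """Assign tracks to condensate bounding-box ROIs.

    ``rois`` are (xmin, xmax, ymin, ymax) rectangles in the track coordinate
    unit.  A track belongs to the ROI containing the largest fraction of its
    localizations, provided that fraction is >= ``min_fraction``; all other
    tracks go to the ``-1`` ("outside") pool.  Returns a (track_id, roi,
    fraction_inside) table.
    """
    rows = []
    for tid, g in tracks.groupby("track_id"):
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        best_roi, best_frac = -1, 0.0
        for i, (xmin, xmax, ymin, ymax) in enumerate(rois):
            inside = ((x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)).mean()
            if inside > best_frac:
                best_roi, best_frac = i, float(inside)
        if best_frac < min_fraction:
            best_roi = -1
        rows.append({"track_id": tid, "roi": best_roi, "fraction_inside": best_frac})
    return pd.DataFrame(rows, columns=["track_id", "roi", "fraction_inside"])


# ---------------------------------------------------------------------------
# MSD and diffusion
# ---------------------------------------------------------------------------

def msd(track: pd.DataFrame, dt: float | None = None,
        max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD of a single track.

    msd(k·dt) = mean over i of |r(i+k) − r(i)|², for k = 1..max_lag
    (default all available lags).  The frame interval is taken from
    ``track.attrs["dt"]`` unless given.
    """
    xy = track[["x", "y"]].to_numpy(dtype=float)
    n = len(xy)
    if n < 2:
        raise ValueError("track must have >= 2 localizations")
    if dt is None:
        dt = track.attrs.get("dt", DEFAULT_DT)
    lags = np.arange(1, n if max_lag is None else min(max_lag, n - 1) + 1)
    values = np.array([np.mean(((xy[k:] - xy[:-k]) ** 2).sum(axis=1)) for k in lags])
    tid = int(track["track_id"].iloc[0]) if "track_id" in track else None
    return MSDCurve(lags=lags * dt, values=values, track_id=tid)


def estimate_D(curve: MSDCurve, fit_lags: int = 4) -> DiffusionEstimate:
    """D from least squares through the origin on MSD = 4·D·t, lags 1..fit_lags."""
    if len(curve.values) < fit_lags:
        raise ValueError(f"MSD curve too short for a {fit_lags}-lag fit")
    t = curve.lags[:fit_lags]
    y = curve.values[:fit_lags]
    slope = float(np.dot(t, y) / np.dot(t, t))
    clipped = slope < 0
    return DiffusionEstimate(D=max(slope / 4.0, 0.0), fit_lags=fit_lags,
                             track_id=curve.track_id, clipped=clipped)


def estimate_D_per_track(tracks: pd.DataFrame, dt: float | None = None,
                         fit_lags: int = 4) -> pd.DataFrame:
    """Per-track diffusion coefficients; returns (track_id, D, clipped)."""
    rows = []
    for tid, g in tracks.groupby("track_id"):
        if len(g) <= fit_lags + 1:
            continue
        est = estimate_D(msd(g, dt=dt, max_lag=fit_lags), fit_lags=fit_lags)
        rows.append({"track_id": tid, "D": est.D, "clipped": est.clipped})
    return pd.DataFrame(rows, columns=["track_id", "D", "clipped"])


# ---------------------------------------------------------------------------
# condensate ROIs from the condensate channel
# ---------------------------------------------------------------------------

def trace_condensate_boundary(condensate_image: np.ndarray, *,
                              smooth_sigma: float = 1.5,
                              min_area: int = 9) -> list[tuple[int, int, int, int]]:
    """Condensate bounding boxes with ridge-line separation between blobs.

    A Laplacian-of-Gaussian response localizes blob interiors; a watershed
    seeded at blob centers and flooded on the LoG response splits adjacent
    condensates along the contiguous intensity minima (ridges) between them.
    Returns (min_row, min_col, max_row, max_col) boxes (half-open), one per
    basin; empty list when nothing is detected.
    """
    img = np.asarray(condensate_image, dtype=float)
    if img.max() == img.min():
        return []
    smoothed = ndi.gaussian_filter(img, smooth_sigma)
    log_resp = -ndi.gaussian_laplace(smoothed, smooth_sigma)  # positive at blobs
    try:
        thr = filters.threshold_otsu(smoothed)
    except ValueError:
        return []
    fg = smoothed > thr
    if not fg.any():
        return []
    peaks = feature.peak_local_max(log_resp, min_distance=3, labels=fg,
                                   exclude_border=False)
    if len(peaks) == 0:
        return []
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    basins = segmentation.watershed(-log_resp, markers, mask=fg)
    boxes = []
    for region in measure.regionprops(basins):
        if region.area < min_area:
            continue
        boxes.append(tuple(int(v) for v in region.bbox))
    return boxes
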