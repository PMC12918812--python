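"""smFISH foci segmentation, knee thresholding and transcription-site calling.

Foci are called per nucleus by an iterative intensity threshold: regional
maxima are counted at every threshold from zero to the image maximum (bin
width 100 intensity units by default), the optimal threshold is the knee of
the resulting count-vs-threshold curve (distance-to-chord, Kneedle-
equivalent), and foci are the 8-connected components above the knee.
Putative transcription sites are the top-k (default 2) foci by total
fluorescent intensity (TFI) in each nucleus; cross-channel TFI evaluates a
focus mask on a second channel (e.g. intron-derived masks on the exon
channel).

Maxima counting and component extraction run on a lightly smoothed image by
default (``smooth_sigma = 1``) so that single-pixel noise maxima do not
dominate the curve; TFI is always the sum of *raw* pixel values over the
component.  Pass ``smooth_sigma=0`` to operate on the raw image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology

__all__ = [
    "ThresholdCurve",
    "KneeResult",
    "threshold_scan",
    "knee_threshold",
    "call_foci",
    "call_transcription_sites",
    "cross_channel_tfi",
]


@dataclass
class ThresholdCurve:
    """Counts of regional maxima exceeding each threshold.

    ``thresholds`` is strictly increasing; ``counts`` is non-increasing.
    """

    thresholds: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if np.any(np.diff(self.counts) > 0):
            raise ValueError("counts must be non-increasing in threshold")


@dataclass
class KneeResult:
    threshold: float
    found: bool  # False = no knee (near-linear curve); threshold is the midpoint


def _analysis_image(image: np.ndarray, smooth_sigma: float) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    return ndi.gaussian_filter(image, smooth_sigma) if smooth_sigma > 0 else image


def _peak_values(image: np.ndarray) -> np.ndarray:
    """Values of regional maxima (one per plateau) of ``image``."""
    peaks = morphology.local_maxima(image, connectivity=2)
    lbl, n = ndi.label(peaks, structure=np.ones((3, 3)))
    if n == 0:
        return np.array([])
    return np.asarray(ndi.maximum(image, lbl, index=np.arange(1, n + 1)))


def threshold_scan(nucleus_image: np.ndarray, bin_width: float = 100.0,
                   smooth_sigma: float = 1.0) -> ThresholdCurve:
    """Count regional maxima above each threshold 0..max in ``bin_width`` steps."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    img = _analysis_image(nucleus_image, smooth_sigma)
    if img.max() == img.min():
        raise ValueError("constant image has no maxima structure")
    thresholds = np.arange(0.0, img.max() + bin_width, bin_width)
    peak_vals = _peak_values(img)
    counts = (peak_vals[None, :] > thresholds[:, None]).sum(axis=1)
    return ThresholdCurve(thresholds=thresholds, counts=counts.astype(int))


def knee_threshold(curve: ThresholdCurve, linear_tol: float = 0.01) -> KneeResult:
    """Knee of a decreasing threshold curve by maximum distance to the chord.

    Both axes are min-max normalized; the knee is the threshold maximizing
    the perpendicular distance to the straight line joining the curve's
    endpoints (the canonical elbow construction for a convex decreasing
    curve).  A curve whose maximum distance is below ``linear_tol`` (i.e.
    essentially linear) has no knee: the midpoint threshold is returned with
    ``found=False``.
    """
    t = np.asarray(curve.thresholds, dtype=float)
    y = np.asarray(curve.counts, dtype=float)
    if len(t) < 3:
        raise ValueError("curve must have at least 3 points")
    tn = (t - t[0]) / (t[-1] - t[0])
    span = y[0] - y[-1]
    if span == 0:
        return KneeResult(threshold=float(t[len(t) // 2]), found=False)
    yn = (y - y[-1]) / span
    # signed distance to the chord from (0, 1) to (1, 0), up to sqrt(2);
    # a decreasing counts curve bends below the chord, so the knee is the
    # maximum of the signed (not absolute) distance
    d = (1.0 - tn) - yn
    i = int(np.argmax(d))
    if d[i] / np.sqrt(2) < linear_tol:
        return KneeResult(threshold=float(t[len(t) // 2]), found=False)
    return KneeResult(threshold=float(t[i]), found=True)


def call_foci(image: np.ndarray, threshold: float, smooth_sigma: float = 1.0,
              min_area: int = 1) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment foci as 8-connected components above ``threshold``.

    Components are found on the (optionally smoothed) analysis image; TFI is
    the sum of raw pixel values over each component.  Returns the focus
    table (focus_id, area, tfi, centroid_row, centroid_col) and the label
    map.  An empty result is valid.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    raw = np.asarray(image, dtype=float)
    img = _analysis_image(raw, smooth_sigma)
    mask = img > threshold
    if min_area > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_area - 1, connectivity=2)
    labels = measure.label(mask, connectivity=2).astype(np.int32)
    rows = []
    # centroids are weighted by the background-subtracted intensity so the
    # position tracks the brightness peak even when a bright site shares its
    # component with background pixels and dimmer neighbours; TFI stays raw
    excess = np.clip(raw - threshold, 0.0, None)
    for region in measure.regionprops(labels, intensity_image=raw):
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        w = excess[rr, cc]
        if w.sum() > 0:
            wr, wc = float((rr * w).sum() / w.sum()), float((cc * w).sum() / w.sum())
        else:
            wr, wc = region.centroid
        rows.append({
            "focus_id": int(region.label),
            "area": int(region.area),
            "tfi": float(region.intensity_mean * region.area),
            "centroid_row": wr,
            "centroid_col": wc,
        })
    table = pd.DataFrame(rows, columns=["focus_id", "area", "tfi",
                                        "centroid_row", "centroid_col"])
    return table, labels


def call_transcription_sites(foci: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Top-k foci by TFI — the putative transcription sites.

    Ties are broken by larger area, then lower focus id.  If fewer than
    ``k`` foci exist all are returned and ``result.attrs["short_count"]``
    is True.  Rows come back ordered by descending TFI with an ``is_ts``
    column set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = foci.sort_values(["tfi", "area", "focus_id"],
                               ascending=[False, False, True], kind="mergesort")
    sites = ordered.head(k).copy()
    sites["is_ts"] = True
    sites = sites.reset_index(drop=True)
    sites.attrs["short_count"] = len(foci) < k
    return sites


def cross_channel_tfi(focus_labels: np.ndarray, other_channel: np.ndarray) -> pd.DataFrame:
    """TFI of each focus pixel set evaluated on another channel.

    ``focus_labels`` is the label map from :func:`call_foci`; the other
    channel must have the same shape.  Returns (focus_id, tfi).
    """
    focus_labels = np.asarray(focus_labels)
    other = np.asarray(other_channel, dtype=float)
    if focus_labels.shape != other.shape:
        raise ValueError("mask and channel shapes differ")
    ids = np.unique(focus_labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return pd.DataFrame(columns=["focus_id", "tfi"])
    sums = ndi.sum_labels(other, labels=focus_labels, index=ids)
    return pd.DataFrame({"focus_id": ids.astype(int), "tfi": np.asarray(sums, dtype=float)})
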