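"""Meta-image and line-scan co-enrichment analysis across condensates.

For each condensate an n×n window (n odd) is cut from every channel around
the condensate centroid; the pixel-wise mean of a window stack is the
*meta-image*, and its min-subtracted main diagonal is the line-scan profile.
Enrichment of a co-imaging channel at condensates is tested by comparing the
per-window sum of co-channel signal within ±`radius` px of the window center
between two groups of windows with a two-sided unpaired t-test.  The null
group comes from a randomized-placement model: condensates sampled from a
control condition are re-placed uniformly onto foci-free nuclei, with
per-nucleus counts drawn from a normal distribution fitted to the control.

Condensate-area distributions across conditions can be matched to a
reference by iterative importance subsampling until a two-sample
Kolmogorov-Smirnov test no longer distinguishes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

__all__ = [
    "WindowStack",
    "MetaImage",
    "PlacementModel",
    "extract_windows",
    "meta_image",
    "linescan",
    "fit_placement_model",
    "randomize_placement",
    "central_sums",
    "central_enrichment_test",
    "area_match",
]


@dataclass
class WindowStack:
    """k windows of n×n pixels centered on condensate centroids."""

    windows: np.ndarray          # (k, n, n)
    centers: np.ndarray          # (k, 2) rounded (row, col)
    edge_flags: np.ndarray       # (k,) True where the window was zero-padded

    @property
    def k(self) -> int:
        return self.windows.shape[0]

    @property
    def n(self) -> int:
        return self.windows.shape[1]


@dataclass
class MetaImage:
    """Pixel-wise mean over a window stack."""

    mean: np.ndarray
    k: int


@dataclass
class PlacementModel:
    """Normal model of per-nucleus condensate counts fitted to a control."""

    mu: float
    sigma: float

    def sample_count(self, rng: np.random.Generator) -> int:
        return max(int(round(rng.normal(self.mu, self.sigma))), 0)


def _centroids(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return records[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    return np.asarray(records, dtype=float).reshape(-1, 2)


def extract_windows(image: np.ndarray, records, n: int = 23) -> WindowStack:
    """Extract n×n windows (n odd) centered at rounded condensate centroids.

    ``records`` is a condensate table with centroid_row/centroid_col columns
    or a (k, 2) array of (row, col) positions.  Windows that touch the image
    border are zero-padded and flagged.
    """
    if n % 2 == 0 or n < 3:
        raise ValueError("window size n must be odd and >= 3")
    image = np.asarray(image, dtype=float)
    centers = np.round(_centroids(records)).astype(int)
    half = n // 2
    k = len(centers)
    windows = np.zeros((k, n, n), dtype=float)
    flags = np.zeros(k, dtype=bool)
    h, w = image.shape
    for i, (r, c) in enumerate(centers):
        r0, r1 = r - half, r + half + 1
        c0, c1 = c - half, c + half + 1
        sr0, sc0 = max(r0, 0), max(c0, 0)
        sr1, sc1 = min(r1, h), min(c1, w)
        if (sr0, sc0, sr1, sc1) != (r0, c0, r1, c1):
            flags[i] = True
        if sr1 > sr0 and sc1 > sc0:
            windows[i, sr0 - r0: sr1 - r0, sc0 - c0: sc1 - c0] = image[sr0:sr1, sc0:sc1]
    return WindowStack(windows=windows, centers=centers, edge_flags=flags)


def meta_image(ws: WindowStack) -> MetaImage:
    """Arithmetic mean over the window stack; requires k >= 1."""
    if ws.k == 0:
        raise ValueError("cannot build a meta-image from zero windows")
    return MetaImage(mean=ws.windows.mean(axis=0), k=ws.k)


def linescan(meta: MetaImage) -> np.ndarray:
    """Background-subtracted (minimum) profile along the main diagonal."""
    profile = np.diagonal(meta.mean).astype(float).copy()
    return profile - profile.min()


# ---------------------------------------------------------------------------
# randomized-placement null
# ---------------------------------------------------------------------------

def fit_placement_model(control_nucleus_records: pd.DataFrame) -> PlacementModel:
    """Fit a normal distribution to per-nucleus condensate counts of a control.

    Requires at least 2 nuclei that contain condensates.
    """
    counts = control_nucleus_records["n_foci"].to_numpy(dtype=float)
    if (counts > 0).sum() < 2:
        raise ValueError("control must contain >= 2 nuclei with condensates")
    return PlacementModel(mu=float(counts.mean()), sigma=float(counts.std(ddof=0)))


def randomize_placement(
    model: PlacementModel,
    foci_free_nuclei: np.ndarray,
    control_records: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Place control condensates at random onto foci-free nuclei.

    For every nucleus in ``foci_free_nuclei`` a count is drawn from the
    placement model (rounded, clipped at 0); that many control condensates
    are sampled with replacement and their centroids re-placed uniformly over
    the nucleus mask eroded by each condensate's equivalent radius, so the
    placed object fits inside the nucleus the way real condensates do.
    Returns a synthetic condensate table (nucleus_id, centroid_row,
    centroid_col, area, source_index).
    """
    foci_free_nuclei = np.asarray(foci_free_nuclei)
    nuc_ids = [i for i in np.unique(foci_free_nuclei) if i != 0]
    if not nuc_ids:
        raise ValueError("no foci-free nuclei to place condensates onto")
    if len(control_records) == 0:
        raise ValueError("control condensate table is empty")
    areas = control_records["area"].to_numpy(dtype=float)
    rows = []
    for nuc_id in nuc_ids:
        nmask = foci_free_nuclei == nuc_id
        depth = ndi.distance_transform_edt(nmask)  # distance to the nuclear rim
        count = model.sample_count(rng)
        picks = rng.integers(0, len(control_records), size=count)
        for idx in picks:
            radius = max(np.sqrt(areas[idx] / np.pi), 1.0)
            interior = depth >= radius
            rr, cc = np.nonzero(interior if interior.any() else nmask)
            j = rng.integers(0, len(rr))
            rows.append({
                "nucleus_id": int(nuc_id),
                "centroid_row": float(rr[j]),
                "centroid_col": float(cc[j]),
                "area": float(areas[idx]),
                "source_index": int(idx),
            })
    return pd.DataFrame(rows, columns=["nucleus_id", "centroid_row", "centroid_col",
                                       "area", "source_index"])


# ---------------------------------------------------------------------------
# central-sum enrichment test
# ---------------------------------------------------------------------------

def central_sums(ws: WindowStack, radius: int = 3) -> np.ndarray:
    """Per-window sum of signal within ±radius px of the window center."""
    if radius < 0 or 2 * radius + 1 > ws.n:
        raise ValueError("radius must satisfy 0 <= 2*radius+1 <= n")
    c = ws.n // 2
    sl = slice(c - radius, c + radius + 1)
    return ws.windows[:, sl, sl].sum(axis=(1, 2))


def central_enrichment_test(
    windows_a: WindowStack,
    windows_b: WindowStack,
    radius: int = 3,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two-sided unpaired t-test on central ±radius box sums of two groups.

    Returns ``(sums_a, sums_b, p)``.  Student's pooled-variance test by
    default; set ``equal_var=False`` for Welch.  Two identical zero-variance
    samples give p = 1.0 by convention.
    """
    if windows_a.n != windows_b.n:
        raise ValueError("window stacks have different sizes")
    if windows_a.k < 2 or windows_b.k < 2:
        raise ValueError("need >= 2 windows per group for a t-test")
    sums_a = central_sums(windows_a, radius)
    sums_b = central_sums(windows_b, radius)
    if sums_a.std() == 0 and sums_b.std() == 0:
        p = 1.0 if sums_a.mean() == sums_b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(sums_a, sums_b, equal_var=equal_var).pvalue)
    return sums_a, sums_b, p


# ---------------------------------------------------------------------------
# area matching across conditions
# ---------------------------------------------------------------------------

def area_match(
    tables_by_condition: dict[str, pd.DataFrame],
    reference: str = "auto",
    p_min: float = 0.05,
    drop_frac: float = 0.05,
    max_iter: int = 50,
    floor_frac: float = 0.15,
    n_bins: int = 32,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Match condensate-area distributions across conditions to a reference.

    The reference is the condition with the lowest mean area (``"auto"``) or
    a named condition.  For every other condition, condensates carry
    importance weights w(a) = density_ref(a) / density_src(a) on shared
    log-spaced histogram bins (zero where the reference has no mass); per
    iteration ``drop_frac`` of the source is removed from the low-weight
    (w < 1, i.e. over-represented) bins, allocated proportionally to each
    bin's excess over the reference shape so no bin is pushed below it,
    with uniformly random victims within a bin.  Densities are recomputed
    each iteration and the loop stops once the two-sample KS p-value
    reaches ``p_min``, the retained fraction falls below ``floor_frac``, or
    ``max_iter`` iterations have run.  Returns the filtered tables plus a
    per-condition report (n_initial, n_retained, ks_p, converged); the seed
    used is recorded in ``report.attrs["seed"]``.
    """
    if len(tables_by_condition) < 2:
        raise ValueError("need at least 2 conditions")
    rng = np.random.default_rng(seed)
    means = {c: t["area"].mean() for c, t in tables_by_condition.items()}
    ref_name = min(means, key=means.get) if reference == "auto" else reference
    if ref_name not in tables_by_condition:
        raise ValueError(f"unknown reference condition {ref_name!r}")
    ref_areas = tables_by_condition[ref_name]["area"].to_numpy(dtype=float)

    all_areas = np.concatenate([t["area"].to_numpy(dtype=float)
                                for t in tables_by_condition.values()])
    lo, hi = np.log(all_areas.min()), np.log(all_areas.max())
    edges = np.exp(np.linspace(lo, hi + 1e-9, n_bins + 1))
    ref_density, _ = np.histogram(ref_areas, bins=edges)
    ref_density = ref_density / max(ref_density.sum(), 1)

    filtered: dict[str, pd.DataFrame] = {ref_name: tables_by_condition[ref_name]}
    report_rows = [{"condition": ref_name, "n_initial": len(ref_areas),
                    "n_retained": len(ref_areas), "ks_p": 1.0, "converged": True,
                    "is_reference": True}]

    for cond, table in tables_by_condition.items():
        if cond == ref_name:
            continue
        src = table.reset_index(drop=True)
        areas = src["area"].to_numpy(dtype=float)
        if areas.max() < ref_areas.min() or areas.min() > ref_areas.max():
            filtered[cond] = src.iloc[0:0]
            report_rows.append({"condition": cond, "n_initial": len(src),
                                "n_retained": 0, "ks_p": 0.0, "converged": False,
                                "is_reference": False})
            continue
        keep = np.ones(len(src), dtype=bool)
        n0 = len(src)
        p = float(stats.ks_2samp(areas, ref_areas).pvalue)
        converged = p >= p_min
        it = 0
        while not converged and it < max_iter and keep.sum() > max(floor_frac * n0, 3):
            it += 1
            cur_idx = np.nonzero(keep)[0]
            cur = areas[cur_idx]
            bin_idx = np.clip(np.searchsorted(edges, cur, side="right") - 1, 0, n_bins - 1)
            src_counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
            # per-bin excess over the reference shape at the current size;
            # items in excess bins have importance weight w = dens_ref/dens_src < 1
            excess = np.maximum(src_counts - ref_density * len(cur), 0.0)
            if excess.sum() == 0:
                break
            n_drop = min(max(int(np.ceil(drop_frac * len(cur))), 1), int(np.ceil(excess.sum())))
            # allocate drops across bins proportional to their excess, never
            # removing a bin below the reference density
            alloc = excess / excess.sum() * n_drop
            per_bin = np.minimum(np.floor(alloc).astype(int), excess.astype(int))
            remainder = alloc - per_bin
            shortfall = n_drop - per_bin.sum()
            if shortfall > 0:
                for j in np.argsort(-remainder):
                    if shortfall == 0:
                        break
                    if per_bin[j] < excess[j]:
                        per_bin[j] += 1
                        shortfall -= 1
            for j in np.nonzero(per_bin)[0]:
                members = cur_idx[bin_idx == j]
                drop = rng.choice(members, size=min(per_bin[j], len(members)), replace=False)
                keep[drop] = False
            p = float(stats.ks_2samp(areas[keep], ref_areas).pvalue)
            converged = p >= p_min
        filtered[cond] = src[keep]
        report_rows.append({"condition": cond, "n_initial": n0,
                            "n_retained": int(keep.sum()), "ks_p": p,
                            "converged": bool(converged), "is_reference": False})

    report = pd.DataFrame(report_rows, columns=["condition", "n_initial", "n_retained",
                                                "ks_p", "converged", "is_reference"])
    report.attrs["seed"] = seed
    return filtered, report
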