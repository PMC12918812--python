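"""Simulation benchmarks: parameter recovery, calibration and power.

Each function runs one self-contained experiment on synthetic data with a
known ground truth and returns the summary statistics a user would quote:
how accurately morphometrics recover the planted partition, whether the
central-sum enrichment test is calibrated under the randomized-placement
null and powered against planted co-enrichment, how well the MSD fit
recovers known diffusion coefficients, the knee-threshold spot
recall/precision, and the exactness of HSE log2FC classification.  The
test suite and the acceptance script both drive these entry points, so the
numbers they report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from condensatekit import fish as fish_mod
from condensatekit import genomics, imaging, metaimage, smt, synthdata

__all__ = [
    "partition_recovery",
    "truth_condensate_table",
    "truth_nucleus_counts",
    "null_calibration",
    "enrichment_power",
    "area_match_benchmark",
    "diffusion_recovery",
    "fish_benchmark",
    "hse_classification_benchmark",
    "hse_null_fraction",
]


def truth_condensate_table(truth: synthdata.SceneTruth) -> pd.DataFrame:
    """Condensate table (centroids/areas) taken from ground-truth masks."""
    rows = []
    for rec in truth.condensates.itertuples():
        mask = truth.condensate_labels == rec.condensate_id
        rows.append({
            "condensate_id": rec.condensate_id,
            "nucleus_id": rec.nucleus_id,
            "centroid_row": rec.row,
            "centroid_col": rec.col,
            "area": int(mask.sum()),
        })
    return pd.DataFrame(rows, columns=["condensate_id", "nucleus_id",
                                       "centroid_row", "centroid_col", "area"])


def truth_nucleus_counts(truth: synthdata.SceneTruth) -> pd.DataFrame:
    """Per-nucleus foci counts from ground truth (for the placement model)."""
    counts = truth.condensates["nucleus_id"].value_counts()
    n = int(truth.nucleus_labels.max())
    return pd.DataFrame({
        "nucleus_id": np.arange(1, n + 1),
        "n_foci": [int(counts.get(i, 0)) for i in range(1, n + 1)],
    })


def _truth_partition(image: np.ndarray, truth: synthdata.SceneTruth) -> float:
    cmask = truth.condensate_labels > 0
    nucleoplasm = (truth.nucleus_labels > 0) & ~cmask
    return float(image[cmask].mean() / image[nucleoplasm].mean())


def partition_recovery(partitions=(1.0, 2.0, 3.0, 5.0), n_nuclei: int = 50,
                       snr: float = 10.0, seed: int = 0) -> pd.DataFrame:
    """Recover the planted partition from truth masks and via segmentation.

    Returns one row per partition with the relative error (%) of the
    truth-mask estimate and of the default-backend segmentation estimate
    (mean apparent partition over nuclei with foci; a partition-1 scene with
    no called foci recovers 1.0 by the no-foci convention).
    """
    rows = []
    for i, p in enumerate(partitions):
        image, truth = synthdata.gen_condensate_scene(
            n_nuclei=n_nuclei, partition=p, snr=snr, seed=seed + i)
        ch = image[0]
        truth_est = _truth_partition(ch, truth)
        nuclei = imaging.segment(ch, "nuclei")
        condensates = imaging.segment(ch, "condensates", nuclei=nuclei)
        table = imaging.condensate_table(ch, nuclei, condensates)
        metrics = imaging.nucleus_metrics(ch, nuclei, condensates, table)
        with_foci = metrics[metrics["n_foci"] > 0]
        seg_est = float(with_foci["apparent_partition"].mean()) if len(with_foci) else 1.0
        rows.append({
            "partition": p,
            "truth_estimate": truth_est,
            "truth_error_pct": abs(truth_est - p) / p * 100,
            "segmentation_estimate": seg_est,
            "segmentation_error_pct": abs(seg_est - p) / p * 100,
        })
    return pd.DataFrame(rows)


def _two_group_scene_pvalue(seed: int, enrichment: float, n_nuclei: int,
                            foci: tuple[float, float], window: int,
                            radius: int) -> float:
    """p-value of condensate windows vs randomized placements on foci-free nuclei."""
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(x) for x in rng.integers(0, 2**31, size=3))
    image, truth = synthdata.gen_condensate_scene(
        n_nuclei=n_nuclei, foci_per_nucleus=foci, partition=3.0,
        cochannel_enrichment=enrichment, snr=10.0, seed=s1)
    null_image, null_truth = synthdata.gen_condensate_scene(
        n_nuclei=n_nuclei, foci_per_nucleus=0, partition=1.0,
        cochannel_enrichment=1.0, snr=10.0, seed=s2)
    table = truth_condensate_table(truth)
    if len(table) < 2:
        return np.nan
    model = metaimage.fit_placement_model(truth_nucleus_counts(truth))
    placed = metaimage.randomize_placement(
        model, null_truth.nucleus_labels, table, np.random.default_rng(s3))
    if len(placed) < 2:
        return np.nan
    ws_cond = metaimage.extract_windows(image[1], table, n=window)
    ws_null = metaimage.extract_windows(null_image[1], placed, n=window)
    _, _, p = metaimage.central_enrichment_test(ws_cond, ws_null, radius=radius)
    return p


def null_calibration(n_repeats: int = 1000, n_nuclei: int = 4,
                     window: int = 23, radius: int = 3,
                     alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I error of the central-sum test under the randomized null.

    Both groups carry no co-enrichment (enrichment = 1); the rejection rate
    at ``alpha`` should match ``alpha``.
    """
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_repeats):
        p = _two_group_scene_pvalue(int(rng.integers(0, 2**31)), enrichment=1.0,
                                    n_nuclei=n_nuclei, foci=(6.0, 1.5),
                                    window=window, radius=radius)
        if np.isfinite(p):
            pvals.append(p)
    pvals = np.asarray(pvals)
    return {
        "n_repeats": len(pvals),
        "rejection_rate": float((pvals < alpha).mean()),
        "alpha": alpha,
    }


def enrichment_power(n_repeats: int = 100, enrichment: float = 2.0,
                     condensates_per_group: int = 200, window: int = 23,
                     radius: int = 3, alpha: float = 0.05, seed: int = 0) -> dict:
    """Detection rate of planted co-enrichment vs the randomized null."""
    # ~8 foci/nucleus; enough nuclei to reach the requested group size
    n_nuclei = max(int(np.ceil(condensates_per_group / 8)), 2)
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_repeats):
        p = _two_group_scene_pvalue(int(rng.integers(0, 2**31)), enrichment=enrichment,
                                    n_nuclei=n_nuclei, foci=(8.0, 1.5),
                                    window=window, radius=radius)
        if np.isfinite(p):
            pvals.append(p)
    pvals = np.asarray(pvals)
    return {
        "n_repeats": len(pvals),
        "detection_rate": float((pvals < alpha).mean()),
        "alpha": alpha,
    }


def area_match_benchmark(n: int = 1000, shift: float = 1.5, sigma: float = 0.4,
                         seed: int = 0) -> dict:
    """Match a +``shift``-scaled lognormal area sample back to its reference.

    Returns the post-match KS p-value, the relative deviation of the matched
    mean from the reference mean, and the retained fraction.
    """
    rng = np.random.default_rng(seed)
    ref = pd.DataFrame({"area": np.exp(rng.normal(np.log(30.0), sigma, size=n))})
    # independent draw with the mean scaled by `shift`
    src = pd.DataFrame({"area": np.exp(rng.normal(np.log(30.0 * shift), sigma, size=n))})
    filtered, report = metaimage.area_match({"ref": ref, "src": src}, seed=seed)
    row = report[report["condition"] == "src"].iloc[0]
    matched_mean = filtered["src"]["area"].mean()
    return {
        "ks_p": float(row["ks_p"]),
        "converged": bool(row["converged"]),
        "mean_rel_dev": float(abs(matched_mean - ref["area"].mean()) / ref["area"].mean()),
        "retained_fraction": float(row["n_retained"] / row["n_initial"]),
        "reference_auto_pick": report[report["is_reference"]]["condition"].iloc[0],
    }


def diffusion_recovery(d_values=(0.05, 0.5, 5.0), n_tracks: int = 500,
                       track_length: int = 100, dt: float = 0.03,
                       loc_noise: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Median relative error of per-track D estimates for known D_true."""
    rows = []
    for i, d_true in enumerate(d_values):
        tracks = synthdata.gen_tracks(
            synthdata.TrackTruth(D_true=d_true, dt=dt, n_tracks=n_tracks,
                                 track_length=track_length,
                                 loc_noise_sigma=loc_noise), seed=seed + i)
        est = smt.estimate_D_per_track(tracks, dt=dt)
        med = float(est["D"].median())
        rows.append({
            "D_true": d_true,
            "D_median": med,
            "median_rel_error": abs(med - d_true) / d_true,
            "n_tracks": len(est),
        })
    return pd.DataFrame(rows)


def fish_benchmark(n_seeds: int = 20, n_spots: int = 40, spot_amp: float = 2000.0,
                   noise_sd: float = 50.0, seed: int = 0) -> pd.DataFrame:
    """Knee-threshold spot recall/precision and TS recovery across seeds.

    Recall: fraction of planted objects overlapped by a called focus within
    3σ of the planted center.  Precision: fraction of called focus pixels
    within 3σ of any planted object.  ts_recovered: both planted
    transcription sites are the top-2 TFI foci (within 2 px).
    """
    rows = []
    for s in range(n_seeds):
        image, truth = synthdata.gen_fish_scene(
            n_spots=n_spots, spot_amp=spot_amp, noise_sd=noise_sd, seed=seed + s)
        curve = fish_mod.threshold_scan(image)
        knee = fish_mod.knee_threshold(curve)
        foci, labels = fish_mod.call_foci(image, knee.threshold)

        yy, xx = np.mgrid[: image.shape[0], : image.shape[1]]
        footprint = np.zeros(image.shape, dtype=bool)
        recalled = 0
        for obj in truth.itertuples():
            disc = (yy - obj.row) ** 2 + (xx - obj.col) ** 2 <= (3 * obj.sigma) ** 2
            footprint |= disc
            if (labels[disc] > 0).any():
                recalled += 1
        called = labels > 0
        precision = float((called & footprint).sum() / called.sum()) if called.any() else 0.0

        sites = fish_mod.call_transcription_sites(foci, k=2)
        ts_truth = truth[truth["kind"] == "ts"]
        matched = 0
        for ts in ts_truth.itertuples():
            d = np.sqrt((sites["centroid_row"] - ts.row) ** 2
                        + (sites["centroid_col"] - ts.col) ** 2)
            if (d <= 2.0).any():
                matched += 1
        rows.append({
            "seed": seed + s,
            "knee": knee.threshold,
            "recall": recalled / len(truth),
            "precision": precision,
            "ts_recovered": matched == len(ts_truth),
        })
    return pd.DataFrame(rows)


def _scaled_track(frags: pd.DataFrame, truth: synthdata.FragmentLibraryTruth):
    spike = int((frags["source"] == "spike").sum())
    factor = genomics.spike_in_factor(spike, len(frags))
    return genomics.coverage(frags[frags["source"] == "target"], scale=factor,
                             chrom_sizes={truth.chrom: truth.genome_length})


def hse_classification_benchmark(n_fragments: int = 50_000, enrichment: float = 4.0,
                                 n_enriched: int = 10, seed: int = 0) -> dict:
    """Classify planted-vs-background HSEs by log2FC against a mock library."""
    mock_truth = synthdata.FragmentLibraryTruth(enrichment_fold=1.0)
    enriched = mock_truth.hse_positions[:n_enriched]
    stress_truth = synthdata.FragmentLibraryTruth(enrichment_fold=enrichment,
                                                  hse_positions=enriched)
    stress = synthdata.gen_fragment_library(stress_truth, n_fragments, seed=seed)
    mock = synthdata.gen_fragment_library(mock_truth, n_fragments, seed=seed + 1)
    hse_set = pd.DataFrame({
        "chrom": mock_truth.chrom,
        "start": [h - 10 for h in mock_truth.hse_positions],
        "end": [h + 10 for h in mock_truth.hse_positions],
        "name": [f"HSE_{i}" for i in range(len(mock_truth.hse_positions))],
        "strand": ".",
    })
    calls = genomics.hse_classify(_scaled_track(stress, stress_truth),
                                  _scaled_track(mock, mock_truth), hse_set)
    planted = np.array([h in enriched for h in mock_truth.hse_positions])
    up = calls["upregulated"].to_numpy()
    return {
        "n_upregulated": int(up.sum()),
        "n_planted": int(planted.sum()),
        "exact": bool((up == planted).all()),
        "min_planted_log2fc": float(calls.loc[planted, "log2fc"].min()),
        "max_background_log2fc": float(calls.loc[~planted, "log2fc"].max()),
    }


def hse_null_fraction(n_hse: int = 1000, n_fragments: int = 50_000,
                      seed: int = 0) -> dict:
    """Fraction of HSEs called upregulated when nothing is planted (≈ 0.5).

    Confirms that the strict > 0 threshold is symmetric under the null.
    Uses a longer genome so the many HSE windows stay disjoint.
    """
    genome = 400_000
    positions = tuple(int(p) for p in (np.arange(n_hse) + 0.5) / n_hse * genome)
    truth = synthdata.FragmentLibraryTruth(genome_length=genome, hse_positions=positions,
                                           enrichment_fold=1.0)
    a = synthdata.gen_fragment_library(truth, n_fragments, seed=seed)
    b = synthdata.gen_fragment_library(truth, n_fragments, seed=seed + 1)
    hse_set = pd.DataFrame({
        "chrom": truth.chrom,
        "start": [p - 10 for p in positions],
        "end": [p + 10 for p in positions],
        "name": [f"H{i}" for i in range(n_hse)],
        "strand": ".",
    })
    calls = genomics.hse_classify(_scaled_track(a, truth), _scaled_track(b, truth), hse_set)
    frac = float(calls["upregulated"].mean())
    lo, hi = stats.binom.interval(0.999, n_hse, 0.5)
    return {"fraction_upregulated": frac, "n_hse": n_hse,
            "binomial_ci_low": lo / n_hse, "binomial_ci_high": hi / n_hse,
            "within_ci": bool(lo / n_hse <= frac <= hi / n_hse)}
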