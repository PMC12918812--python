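"""Ground-truthed synthetic data emulating the study's imaging and sequencing inputs.

Every generator is deterministic given its seed and returns, alongside the
data, a truth object from which the parameters it was asked to plant can be
recomputed directly.  Four input modalities are covered:

* two-channel condensate scenes (nuclei with bright foci at a controlled
  partition ratio and co-channel enrichment),
* single-nucleus smFISH images (diffraction-limited spots plus two bright
  transcription sites),
* Brownian single-molecule trajectories confined to a box,
* paired-end fragment libraries with bimodal lengths, enrichment at
  heat-shock-element (HSE) loci and an *E. coli*-style spike-in population.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "SceneTruth",
    "TrackTruth",
    "FragmentLibraryTruth",
    "gen_condensate_scene",
    "gen_fish_scene",
    "gen_tracks",
    "gen_fragment_library",
    "write_scene",
]

#: default mean fluorescence of the nucleoplasm, camera units
NUCLEOPLASM_LEVEL = 200.0
#: default extranuclear background, camera units
BACKGROUND_LEVEL = 20.0
#: default pixel pitch, µm/px (configurable; required for SMT unit conversion)
PIXEL_SIZE_UM = 0.1
#: fraction of the peak at which the rendered (Gaussian-blurred) condensate
#: footprint is cut to form its truth mask
_MASK_CONTOUR = 0.05


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class SceneTruth:
    """Ground truth of a two-channel condensate scene.

    ``nucleus_labels`` and ``condensate_labels`` are integer label maps
    (0 = background); every condensate mask is a subset of exactly one nucleus
    mask and masks are pairwise disjoint.  ``condensates`` holds one row per
    condensate (condensate_id, nucleus_id, row, col, radius).
    """

    nucleus_labels: np.ndarray
    condensate_labels: np.ndarray
    condensates: pd.DataFrame
    partition: float
    cochannel_enrichment: float
    seed: int
    nucleoplasm_level: float = NUCLEOPLASM_LEVEL
    pixel_size: float = PIXEL_SIZE_UM


@dataclass
class TrackTruth:
    """Parameters of a Brownian track ensemble.

    D_true in µm²/s, dt in s (default 30 ms/frame), localization error in µm.
    ``box`` is an axis-aligned confinement rectangle (xmin, xmax, ymin, ymax)
    in µm, or None for free diffusion.  ``track_length`` is either a fixed
    frame count or an inclusive (lo, hi) range sampled uniformly.
    """

    D_true: float = 0.5
    dt: float = 0.03
    loc_noise_sigma: float = 0.0
    box: tuple[float, float, float, float] | None = None
    n_tracks: int = 100
    track_length: int | tuple[int, int] = 100

    def __post_init__(self) -> None:
        if not math.isfinite(self.D_true) or self.D_true < 0:
            raise ValueError("D_true must be finite and >= 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.loc_noise_sigma < 0:
            raise ValueError("loc_noise_sigma must be >= 0")
        lo = self.track_length if isinstance(self.track_length, int) else self.track_length[0]
        if lo < 2:
            raise ValueError("track lengths must be >= 2")
        if self.box is not None:
            xmin, xmax, ymin, ymax = self.box
            if not (xmax > xmin and ymax > ymin):
                raise ValueError("confinement box must have positive extent")


@dataclass
class FragmentLibraryTruth:
    """Parameters of a synthetic fragment library.

    The genome is a single scaled-down chromosome (``chrom``); HSE loci are
    point anchors around which fragments are enriched ``enrichment_fold``-fold
    within a capture window of ``hse_window`` bp.  Fragment lengths come from
    a two-mode normal mixture (transcription-factor-footprint-sized short mode
    and nucleosome-sized long mode).  A ``spike_fraction`` of fragments is
    drawn from a separate spike-in chromosome.
    """

    genome_length: int = 20_000
    hse_positions: tuple[int, ...] | None = None
    enrichment_fold: float = 1.0
    fraglen_modes: tuple[tuple[float, float], tuple[float, float]] = ((80.0, 10.0), (180.0, 15.0))
    fraglen_weights: tuple[float, float] = (0.5, 0.5)
    spike_fraction: float = 0.05
    hse_window: int = 200
    chrom: str = "chrSim"
    spike_chrom: str = "chrSpike"
    spike_genome_length: int = 10_000

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 <= self.spike_fraction < 1:
            raise ValueError("spike_fraction must be in [0, 1)")
        if self.enrichment_fold < 0:
            raise ValueError("enrichment_fold must be >= 0")
        if self.hse_positions is None:
            # 20 evenly spaced anchors, ~1 kb apart at the default genome size
            n = 20
            pos = ((np.arange(n) + 0.5) / n * self.genome_length).astype(int)
            object.__setattr__(self, "hse_positions", tuple(int(p) for p in pos))
        for p in self.hse_positions:
            if not 0 <= p < self.genome_length:
                raise ValueError(f"HSE position {p} outside genome [0, {self.genome_length})")


# ---------------------------------------------------------------------------
# condensate scenes
# ---------------------------------------------------------------------------

def _check_finite(**params: float) -> None:
    for name, value in params.items():
        if not math.isfinite(float(value)):
            raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


def _draw_count(rng: np.random.Generator, spec: int | tuple[float, float]) -> int:
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    mu, sigma = spec
    return max(int(round(rng.normal(mu, sigma))), 0)


def _sample_nuclei(rng, n_nuclei, shape):
    """Rejection-sample non-overlapping ellipse parameters (cy, cx, a, b, theta)."""
    h, w = shape
    nuclei = []
    attempts = 0
    while len(nuclei) < n_nuclei:
        attempts += 1
        if attempts > 50_000:
            raise RuntimeError("could not place non-overlapping nuclei; canvas too small")
        a = rng.uniform(20.0, 27.0)   # semi-major, px
        b = rng.uniform(15.0, 21.0)   # semi-minor, px
        theta = rng.uniform(0.0, np.pi)
        cy = rng.uniform(a + 3, h - a - 3)
        cx = rng.uniform(a + 3, w - a - 3)
        ok = all((cy - oy) ** 2 + (cx - ox) ** 2 > (a + oa + 4) ** 2 for oy, ox, oa, _, _ in nuclei)
        if ok:
            nuclei.append((cy, cx, a, b, theta))
    return nuclei


def _ellipse_mask(shape, cy, cx, a, b, theta):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    dy, dx = yy - cy, xx - cx
    u = dy * np.sin(theta) + dx * np.cos(theta)
    v = dy * np.cos(theta) - dx * np.sin(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _point_in_ellipse(rng, cy, cx, a, b, theta, margin):
    """Uniform point in the ellipse shrunk by ``margin`` on each semi-axis."""
    ae, be = max(a - margin, 1.0), max(b - margin, 1.0)
    while True:
        u = rng.uniform(-ae, ae)
        v = rng.uniform(-be, be)
        if (u / ae) ** 2 + (v / be) ** 2 <= 1.0:
            row = cy + u * np.sin(theta) + v * np.cos(theta)
            col = cx + u * np.cos(theta) - v * np.sin(theta)
            return row, col


def _blurred_disc(radius: float, blur_sigma: float = 1.0):
    """Gaussian-blurred disc template and its truth mask (>= contour of peak)."""
    pad = int(np.ceil(radius + 4 * blur_sigma)) + 1
    size = 2 * pad + 1
    yy, xx = np.ogrid[:size, :size]
    disc = ((yy - pad) ** 2 + (xx - pad) ** 2 <= radius**2).astype(float)
    blurred = ndi.gaussian_filter(disc, blur_sigma)
    mask = blurred >= _MASK_CONTOUR * blurred.max()
    return blurred, mask, pad


def gen_condensate_scene(
    n_nuclei: int = 12,
    foci_per_nucleus: int | tuple[float, float] = (5.0, 1.5),
    partition: float = 3.0,
    cochannel_enrichment: float = 1.0,
    snr: float = 10.0,
    seed: int = 0,
    *,
    nucleoplasm_level: float = NUCLEOPLASM_LEVEL,
    background_level: float = BACKGROUND_LEVEL,
    condensate_radius: tuple[float, float] = (3.0, 6.0),
    pixel_size: float = PIXEL_SIZE_UM,
) -> tuple[np.ndarray, SceneTruth]:
    """Render a two-channel fluorescence scene with planted condensates.

    Channel 0 carries the condensate marker at the requested ``partition``
    (ratio of in-condensate to nucleoplasmic mean); channel 1 carries a
    co-imaging signal at ``cochannel_enrichment`` over the same masks
    (1 = flat, i.e. no co-enrichment).  Condensates are Gaussian-blurred
    discs inside non-overlapping elliptical nuclei; noise is Poisson shot
    noise plus Gaussian read noise, with ``snr`` defined as
    (condensate mean − nucleoplasm mean) / noise SD (nucleoplasm mean / SD
    in the ``partition == 1`` degenerate case).

    Returns ``(image, truth)`` where ``image`` has shape (2, H, W) and
    ``truth`` is a :class:`SceneTruth` carrying label maps and a per-
    condensate table.
    """
    _check_finite(partition=partition, cochannel_enrichment=cochannel_enrichment, snr=snr)
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    if partition < 1:
        raise ValueError("partition must be >= 1")
    if cochannel_enrichment < 0:
        raise ValueError("cochannel_enrichment must be >= 0")
    if not snr > 0:
        raise ValueError("snr must be > 0")

    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_nuclei)) * 130) + 60
    shape = (side, side)
    nuclei = _sample_nuclei(rng, n_nuclei, shape)

    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cond_labels = np.zeros(shape, dtype=np.int32)
    ch0 = np.full(shape, background_level, dtype=float)
    ch1 = np.full(shape, background_level, dtype=float)

    amp0 = (partition - 1.0) * nucleoplasm_level
    amp1 = (cochannel_enrichment - 1.0) * nucleoplasm_level

    rows = []
    cond_id = 0
    for nuc_id, (cy, cx, a, b, theta) in enumerate(nuclei, start=1):
        nmask = _ellipse_mask(shape, cy, cx, a, b, theta)
        nucleus_labels[nmask] = nuc_id
        ch0[nmask] = nucleoplasm_level
        ch1[nmask] = nucleoplasm_level

        n_foci = _draw_count(rng, foci_per_nucleus)
        placed: list[tuple[float, float, float]] = []
        for _ in range(n_foci):
            radius = rng.uniform(*condensate_radius)
            r_eff = radius + 3.0  # truth-mask halo margin
            for _attempt in range(200):
                row, col = _point_in_ellipse(rng, cy, cx, a, b, theta, r_eff + 1.0)
                if all((row - pr) ** 2 + (col - pc) ** 2 > (r_eff + pe + 1) ** 2
                       for pr, pc, pe in placed):
                    break
            else:
                continue  # nucleus too crowded; skip this focus
            placed.append((row, col, r_eff))
            cond_id += 1

            blurred, mask, pad = _blurred_disc(radius)
            r0, c0 = int(round(row)) - pad, int(round(col)) - pad
            # clip the template to the canvas (placement margins normally keep
            # it fully inside; this guards the off-by-a-pixel cases)
            tr0, tc0 = max(-r0, 0), max(-c0, 0)
            tr1 = blurred.shape[0] - max(r0 + blurred.shape[0] - shape[0], 0)
            tc1 = blurred.shape[1] - max(c0 + blurred.shape[1] - shape[1], 0)
            sl = (slice(r0 + tr0, r0 + tr1), slice(c0 + tc0, c0 + tc1))
            tsl = (slice(tr0, tr1), slice(tc0, tc1))
            unit = blurred / blurred[mask].mean()  # mean over truth mask == 1
            ch0[sl] += amp0 * unit[tsl]
            ch1[sl] += amp1 * unit[tsl]
            cond_labels[sl][mask[tsl]] = cond_id
            rows.append({"condensate_id": cond_id, "nucleus_id": nuc_id,
                         "row": row, "col": col, "radius": radius})

    # masks stay inside their nucleus by the placement margin; enforce anyway
    cond_labels[nucleus_labels == 0] = 0

    # noise is sized per channel from that channel's own planted contrast
    # (nucleoplasm level in the flat degenerate cases), so scenes that differ
    # only in the *other* channel share identical noise statistics
    contrast0 = amp0 if partition > 1 else nucleoplasm_level
    contrast1 = abs(amp1) if cochannel_enrichment != 1 else nucleoplasm_level
    img = np.stack([ch0, ch1]).astype(float)
    noisy = rng.poisson(np.clip(img, 0, None)).astype(float)
    for ch, contrast in enumerate((contrast0, contrast1)):
        read_var = max((contrast / snr) ** 2 - nucleoplasm_level, 0.0)
        if read_var > 0:  # Poisson shot noise supplies the rest
            noisy[ch] += rng.normal(0.0, np.sqrt(read_var), size=noisy[ch].shape)

    truth = SceneTruth(
        nucleus_labels=nucleus_labels,
        condensate_labels=cond_labels,
        condensates=pd.DataFrame(rows, columns=["condensate_id", "nucleus_id", "row", "col", "radius"]),
        partition=float(partition),
        cochannel_enrichment=float(cochannel_enrichment),
        seed=int(seed),
        nucleoplasm_level=float(nucleoplasm_level),
        pixel_size=float(pixel_size),
    )
    return noisy, truth


# ---------------------------------------------------------------------------
# smFISH scenes
# ---------------------------------------------------------------------------

def gen_fish_scene(
    n_spots: int = 40,
    spot_amp: float = 2000.0,
    ts_amp: float = 20000.0,
    bg: float = 200.0,
    seed: int = 0,
    *,
    noise_sd: float = 50.0,
    shape: tuple[int, int] = (256, 256),
    spot_sigma: tuple[float, float] = (1.0, 1.8),
    ts_sigma: float = 2.2,
    n_ts: int = 2,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a single-nucleus smFISH image with planted spots and TS.

    Diffraction-limited Gaussian spots of amplitude ``spot_amp`` are placed
    uniformly; ``n_ts`` bright transcription-site blobs of amplitude
    ``ts_amp`` are planted so that, by construction, they are the objects
    with the largest total intensity.  The returned truth table has columns
    (kind, row, col, sigma, amplitude, tfi) with analytic total intensity
    2π·σ²·amplitude; ``truth.attrs["crowding_warning"]`` flags scenes in
    which > 20 % of spots sit closer than 3σ to a neighbour.
    """
    if not ts_amp > spot_amp > bg >= 0:
        raise ValueError("require ts_amp > spot_amp > bg >= 0")
    if n_spots < 0:
        raise ValueError("n_spots must be >= 0")

    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, float(bg))
    yy, xx = np.mgrid[:h, :w]

    margin = 12
    rows = []
    for _ in range(n_spots):
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        s = rng.uniform(*spot_sigma)
        rows.append({"kind": "spot", "row": r, "col": c, "sigma": s, "amplitude": spot_amp})
    for _ in range(n_ts):
        # transcription sites model distinct alleles: kept away from the
        # border and far enough apart that their footprints cannot merge
        for _attempt in range(200):
            r = rng.uniform(margin + 8, h - margin - 8)
            c = rng.uniform(margin + 8, w - margin - 8)
            if all((r - q["row"]) ** 2 + (c - q["col"]) ** 2 > 35**2
                   for q in rows if q["kind"] == "ts"):
                break
        rows.append({"kind": "ts", "row": r, "col": c, "sigma": ts_sigma, "amplitude": ts_amp})

    for q in rows:
        img += q["amplitude"] * np.exp(
            -((yy - q["row"]) ** 2 + (xx - q["col"]) ** 2) / (2 * q["sigma"] ** 2)
        )
    img += rng.normal(0.0, noise_sd, size=shape)

    truth = pd.DataFrame(rows, columns=["kind", "row", "col", "sigma", "amplitude"])
    truth["tfi"] = 2 * np.pi * truth["sigma"] ** 2 * truth["amplitude"]

    crowded = 0
    spots = truth[truth["kind"] == "spot"]
    if len(spots) > 1:
        pts = spots[["row", "col"]].to_numpy()
        sig = spots["sigma"].to_numpy()
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        crowded = int((np.sqrt(d2.min(1)) < 3 * sig).sum())
    truth.attrs["crowding_warning"] = bool(n_spots and crowded / max(n_spots, 1) > 0.2)
    return img, truth


# ---------------------------------------------------------------------------
# Brownian tracks
# ---------------------------------------------------------------------------

def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (billiard boundary)."""
    span = hi - lo
    out = np.mod(pos - lo, 2 * span)
    out = np.where(out > span, 2 * span - out, out)
    return out + lo


def gen_tracks(truth: TrackTruth, seed: int = 0) -> pd.DataFrame:
    """Simulate Brownian trajectories; returns a (track_id, frame, x, y) table in µm.

    Per-axis step displacements are Normal(0, 2·D·dt); positions are reflected
    at the confinement walls if a box is set, and independent localization
    noise of SD ``loc_noise_sigma`` is added to the reported coordinates.
    The frame interval is attached as ``tracks.attrs["dt"]``.
    """
    rng = np.random.default_rng(seed)
    step_sd = math.sqrt(2.0 * truth.D_true * truth.dt)
    frames = []
    for tid in range(truth.n_tracks):
        if isinstance(truth.track_length, int):
            n = truth.track_length
        else:
            n = int(rng.integers(truth.track_length[0], truth.track_length[1] + 1))
        if truth.box is not None:
            xmin, xmax, ymin, ymax = truth.box
            x0 = rng.uniform(xmin, xmax)
            y0 = rng.uniform(ymin, ymax)
        else:
            x0 = y0 = 0.0
        steps = rng.normal(0.0, step_sd, size=(n - 1, 2)) if step_sd > 0 else np.zeros((n - 1, 2))
        xy = np.concatenate([[[x0, y0]], steps]).cumsum(axis=0)
        if truth.box is not None:
            xy[:, 0] = _reflect(xy[:, 0], xmin, xmax)
            xy[:, 1] = _reflect(xy[:, 1], ymin, ymax)
        if truth.loc_noise_sigma > 0:
            xy = xy + rng.normal(0.0, truth.loc_noise_sigma, size=xy.shape)
        frames.append(pd.DataFrame({
            "track_id": tid,
            "frame": np.arange(n),
            "x": xy[:, 0],
            "y": xy[:, 1],
        }))
    tracks = pd.concat(frames, ignore_index=True)
    tracks.attrs["dt"] = truth.dt
    tracks.attrs["unit"] = "um"
    return tracks


# ---------------------------------------------------------------------------
# fragment libraries
# ---------------------------------------------------------------------------

def gen_fragment_library(
    truth: FragmentLibraryTruth,
    n_fragments: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a fragment library with HSE enrichment and a spike-in population.

    Fragment midpoints are uniform over the genome except within
    ``truth.hse_window`` bp of an HSE anchor, where the *density* is exactly
    ``enrichment_fold``-fold the uniform background; the total fragment count
    is fixed (fixed sequencing depth), so enrichment redistributes mass.
    Lengths are drawn from the two-mode normal mixture.  A Bernoulli
    ``spike_fraction`` of fragments is instead placed uniformly on the
    spike-in chromosome.  Coordinates are 0-based half-open.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)

    lengths = _draw_lengths(rng, truth, n_fragments)
    is_spike = rng.random(n_fragments) < truth.spike_fraction

    g = truth.genome_length
    e = truth.enrichment_fold
    half_w = truth.hse_window / 2.0
    hse = np.asarray(truth.hse_positions, dtype=float)
    # probability a fragment is drawn from an HSE capture window such that the
    # density there is exactly e-fold the uniform background
    extra_mass = (e - 1.0) * len(hse) * truth.hse_window
    q = extra_mass / (g + extra_mass) if extra_mass > 0 else 0.0

    n = n_fragments
    from_hse = rng.random(n) < q
    mid = rng.uniform(0, g, size=n)
    if from_hse.any():
        k = int(from_hse.sum())
        which = rng.integers(0, len(hse), size=k)
        mid[from_hse] = hse[which] + rng.uniform(-half_w, half_w, size=k)

    start = np.clip(np.round(mid - lengths / 2).astype(int), 0, None)
    end = np.minimum(start + lengths, g)
    start = np.minimum(start, end - 1)

    # spike-in fragments: uniform on the spike chromosome
    if is_spike.any():
        k = int(is_spike.sum())
        slen = np.minimum(lengths[is_spike], truth.spike_genome_length - 1)
        sstart = rng.integers(0, np.maximum(truth.spike_genome_length - slen, 1))
        start[is_spike] = sstart
        end[is_spike] = sstart + slen

    frags = pd.DataFrame({
        "chrom": np.where(is_spike, truth.spike_chrom, truth.chrom),
        "start": start,
        "end": end,
        "source": np.where(is_spike, "spike", "target"),
    })
    frags.attrs["chrom_sizes"] = {
        truth.chrom: truth.genome_length,
        truth.spike_chrom: truth.spike_genome_length,
    }
    return frags


def _draw_lengths(rng, truth: FragmentLibraryTruth, n: int) -> np.ndarray:
    w = np.asarray(truth.fraglen_weights, dtype=float)
    w = w / w.sum()
    comp = rng.random(n) < w[0]
    (m0, s0), (m1, s1) = truth.fraglen_modes
    lengths = np.where(comp, rng.normal(m0, s0, n), rng.normal(m1, s1, n))
    return np.clip(np.round(lengths).astype(int), 20, None)


# ---------------------------------------------------------------------------
# on-disk representation
# ---------------------------------------------------------------------------

def write_scene(path_prefix, image: np.ndarray, truth: SceneTruth) -> dict[str, str]:
    """Write a scene as multi-page TIFF plus TSV truth tables; returns the paths."""
    import tifffile

    from pathlib import Path

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": str(prefix) + ".tif",
        "nuclei": str(prefix) + ".nuclei.tif",
        "condensates": str(prefix) + ".condensates.tif",
        "truth": str(prefix) + ".truth.tsv",
    }
    tifffile.imwrite(paths["image"], image.astype(np.float32))
    tifffile.imwrite(paths["nuclei"], truth.nucleus_labels.astype(np.uint16))
    tifffile.imwrite(paths["condensates"], truth.condensate_labels.astype(np.uint16))
    truth.condensates.to_csv(paths["truth"], sep="\t", index=False)
    return paths
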