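"""Spike-in-normalized coverage, fragment classes, metaplots and HSE calls.

Fragments are 0-based half-open intervals (chrom, start, end, source) as a
DataFrame; coverage is per-base fragment-span depth multiplied by a scale
factor (normally the spike-in factor 1/(spike reads / total reads)).
Fragment-length classes follow the factor-vs-nucleosome footprint split:
short ≤ 120 bp, long ≥ 150 bp, with the 121–149 bp middle kept separate and
excluded from both.  Metaprofiles average spike-scaled signal across loci
(anchor = interval midpoint for HSEs, the annotated TSS for genes;
minus-strand loci reversed) and then across replicates.  Heat-shock-element
(HSE) regulation is classified by log2 fold change of mean signal within
±window bp of each HSE between a stress and a mock track (pseudocount on
both), upregulated iff log2FC > 0; per-locus background for plotting is the
minimum signal within ±1 kb of the anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "MetaProfile",
    "classify_fragments",
    "spike_in_factor",
    "coverage",
    "metaprofile",
    "hse_classify",
    "background_subtract",
    "read_bed",
    "write_bed",
    "read_fragments",
    "write_fragments",
    "read_bedgraph",
    "write_bedgraph",
]

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


@dataclass
class CoverageTrack:
    """Per-base (bin = 1) scaled fragment coverage, one array per chromosome."""

    values: dict[str, np.ndarray]
    scale: float = 1.0

    def chrom_size(self, chrom: str) -> int:
        return len(self.values[chrom])


@dataclass
class MetaProfile:
    """Mean signal at positions −flank..+flank relative to locus anchors."""

    positions: np.ndarray
    values: np.ndarray
    n_loci: int
    n_replicates: int


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def _validate_fragments(frags: pd.DataFrame) -> None:
    if not ((frags["start"] >= 0) & (frags["start"] < frags["end"])).all():
        raise ValueError("fragments must satisfy 0 <= start < end")


def classify_fragments(frags: pd.DataFrame, short_max: int = 120,
                       long_min: int = 150) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition fragments into (short ≤ short_max, long ≥ long_min, middle).

    The middle class (121–149 bp at the defaults) is returned separately and
    belongs to neither footprint class.
    """
    _validate_fragments(frags)
    length = frags["end"] - frags["start"]
    short = frags[length <= short_max]
    long = frags[length >= long_min]
    middle = frags[(length > short_max) & (length < long_min)]
    return short, long, middle


def spike_in_factor(spike_reads: int, total_reads: int) -> float:
    """Spike-in scale factor 1 / (spike reads / total reads)."""
    if spike_reads <= 0:
        raise ValueError("spike-in factor undefined for zero spike-in reads")
    if spike_reads > total_reads:
        raise ValueError("spike reads cannot exceed total reads")
    return 1.0 / (spike_reads / total_reads)


def coverage(frags: pd.DataFrame, scale: float = 1.0,
             chrom_sizes: dict[str, int] | None = None,
             bin: int = 1) -> CoverageTrack:
    """Per-base count of overlapping full fragment spans, times ``scale``.

    ``chrom_sizes`` defaults to ``frags.attrs["chrom_sizes"]`` or the maximum
    fragment end per chromosome.  Fragments extending beyond the declared
    chromosome length are clipped with a warning.  Only bin = 1 is
    implemented (the exchange resolution used throughout).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if bin != 1:
        raise NotImplementedError("only bin size 1 is supported")
    _validate_fragments(frags)
    if chrom_sizes is None:
        chrom_sizes = frags.attrs.get("chrom_sizes") or {
            c: int(g["end"].max()) for c, g in frags.groupby("chrom")
        }
    values: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        sub = frags[frags["chrom"] == chrom]
        diff = np.zeros(size + 1, dtype=float)
        starts = sub["start"].to_numpy(dtype=int)
        ends = sub["end"].to_numpy(dtype=int)
        if (ends > size).any():
            warnings.warn(f"{int((ends > size).sum())} fragments beyond {chrom} length; clipped")
            ends = np.minimum(ends, size)
            starts = np.minimum(starts, ends - 1)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        values[chrom] = np.cumsum(diff[:-1]) * scale
    return CoverageTrack(values=values, scale=float(scale))


# ---------------------------------------------------------------------------
# metaprofiles
# ---------------------------------------------------------------------------

def _anchor_positions(loci: pd.DataFrame, anchor: str) -> np.ndarray:
    if anchor == "midpoint":
        return ((loci["start"] + loci["end"]) // 2).to_numpy(dtype=int)
    if anchor == "tss":
        strand = loci.get("strand", pd.Series(["+"] * len(loci)))
        return np.where(strand == "-", loci["end"] - 1, loci["start"]).astype(int)
    raise ValueError("anchor must be 'midpoint' or 'tss'")


def _extract_locus(track_values: np.ndarray, center: int, flank: int,
                   minus_strand: bool) -> tuple[np.ndarray, bool]:
    lo, hi = center - flank, center + flank + 1
    clipped_lo, clipped_hi = max(lo, 0), min(hi, len(track_values))
    out = np.zeros(2 * flank + 1, dtype=float)
    flagged = (clipped_lo, clipped_hi) != (lo, hi)
    out[clipped_lo - lo: clipped_hi - lo] = track_values[clipped_lo:clipped_hi]
    if minus_strand:
        out = out[::-1]
    return out, flagged


def locus_matrix(track: CoverageTrack, loci: pd.DataFrame, flank: int,
                 anchor: str = "midpoint") -> np.ndarray:
    """(n_loci, 2·flank+1) per-locus signal matrix, strand-oriented."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if len(loci) == 0:
        raise ValueError("loci set is empty")
    centers = _anchor_positions(loci, anchor)
    strand = loci.get("strand", pd.Series(["+"] * len(loci))).to_numpy()
    rows = []
    n_flagged = 0
    for chrom, center, s in zip(loci["chrom"], centers, strand):
        vals = track.values[chrom]
        row, flagged = _extract_locus(vals, int(center), flank, s == "-")
        n_flagged += flagged
        rows.append(row)
    mat = np.array(rows)
    if n_flagged:
        warnings.warn(f"{n_flagged} loci extended beyond the chromosome; zero-padded")
    return mat


def metaprofile(tracks: list[CoverageTrack] | CoverageTrack, loci: pd.DataFrame,
                flank: int = 2000, anchor: str = "midpoint") -> MetaProfile:
    """Mean signal profile across loci, then across replicate tracks.

    The anchor is the interval midpoint for HSE-style loci or the annotated
    TSS (strand-aware) for gene lists; minus-strand loci are reversed so
    that positive positions read downstream.
    """
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    per_rep = [locus_matrix(t, loci, flank, anchor).mean(axis=0) for t in tracks]
    values = np.mean(per_rep, axis=0)
    return MetaProfile(positions=np.arange(-flank, flank + 1), values=values,
                       n_loci=len(loci), n_replicates=len(tracks))


def hse_classify(stress_track: CoverageTrack, mock_track: CoverageTrack,
                 hse_set: pd.DataFrame, window: int = 50,
                 pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-HSE log2 fold change of mean ±window signal, stress vs mock.

    log2FC = log2((mean stress + ε) / (mean mock + ε)); upregulated iff
    log2FC > 0 (strict).  Returns (chrom, start, end, name, log2fc,
    upregulated).
    """
    stress = locus_matrix(stress_track, hse_set, window).mean(axis=1)
    mock = locus_matrix(mock_track, hse_set, window).mean(axis=1)
    log2fc = np.log2((stress + pseudocount) / (mock + pseudocount))
    out = hse_set.reset_index(drop=True).copy()
    out["log2fc"] = log2fc
    out["upregulated"] = log2fc > 0
    return out


def background_subtract(profile_matrix: np.ndarray, positions: np.ndarray,
                        bg_flank: int = 1000) -> np.ndarray:
    """Subtract each locus's minimum signal within ±bg_flank of its anchor.

    ``profile_matrix`` is (n_loci, n_positions) with ``positions`` relative
    to the anchor; the subtracted minimum is computed over the positions
    within [−bg_flank, +bg_flank] (all positions if the profile is narrower).
    """
    mat = np.asarray(profile_matrix, dtype=float)
    positions = np.asarray(positions)
    if mat.ndim == 1:
        mat = mat[None, :]
    if mat.shape[1] != len(positions):
        raise ValueError("positions length must match profile width")
    sel = np.abs(positions) <= bg_flank
    if not sel.any():
        raise ValueError("background region is outside the profile")
    mins = mat[:, sel].min(axis=1, keepdims=True)
    out = mat - mins
    return out[0] if profile_matrix.ndim == 1 else out


# ---------------------------------------------------------------------------
# I/O plumbing (BED / bedGraph / fragment TSV)
# ---------------------------------------------------------------------------

def read_bed(path, one_based: bool = False) -> pd.DataFrame:
    """Read a 3–6 column BED file into (chrom, start, end, name, score, strand).

    Coordinates are validated as 0-based half-open.  With ``one_based=True``
    inputs are converted (start − 1) and a note is recorded in
    ``result.attrs["converted_from_one_based"]``.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has < 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            if not 0 <= start < end:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            rows.append({
                "chrom": parts[0], "start": start, "end": end,
                "name": parts[3] if len(parts) > 3 else ".",
                "score": parts[4] if len(parts) > 4 else ".",
                "strand": strand,
            })
    out = pd.DataFrame(rows, columns=list(BED_COLUMNS))
    out.attrs["converted_from_one_based"] = bool(one_based)
    return out


def write_bed(loci: pd.DataFrame, path) -> None:
    """Write (chrom, start, end[, name, score, strand]) as BED."""
    cols = [c for c in BED_COLUMNS if c in loci.columns]
    loci[cols].to_csv(path, sep="\t", header=False, index=False)


def read_fragments(path) -> pd.DataFrame:
    """Read a fragment TSV (chrom, start, end, source) with validation."""
    frags = pd.read_csv(path, sep="\t", dtype={"chrom": str, "source": str})
    expected = {"chrom", "start", "end", "source"}
    if not expected.issubset(frags.columns):
        raise ValueError(f"{path}: fragment table must have columns {sorted(expected)}")
    _validate_fragments(frags)
    bad = ~frags["source"].isin(["target", "spike"])
    if bad.any():
        raise ValueError(f"{path}: invalid source at data row {int(np.argmax(bad.to_numpy())) + 1}")
    return frags


def write_fragments(frags: pd.DataFrame, path) -> None:
    frags[["chrom", "start", "end", "source"]].to_csv(path, sep="\t", index=False)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a coverage track as 4-column bedGraph with run-length merging."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            if len(vals) == 0:
                continue
            change = np.nonzero(np.diff(vals))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int] | None = None) -> CoverageTrack:
    """Read a 4-column bedGraph into a per-base CoverageTrack."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph line must have 4 columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if not 0 <= s < e:
                raise ValueError(f"{path}:{lineno}: invalid interval")
            intervals.setdefault(chrom, []).append((s, e, v))
    sizes = chrom_sizes or {c: max(e for _, e, _ in iv) for c, iv in intervals.items()}
    values = {c: np.zeros(n, dtype=float) for c, n in sizes.items()}
    for chrom, iv in intervals.items():
        for s, e, v in iv:
            values[chrom][s:e] = v
    return CoverageTrack(values=values, scale=1.0)
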