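"""Configuration-driven orchestration of the analysis stages.

A single TOML config with per-stage sections drives an end-to-end run on
synthetic data: synthdata → imaging → metaimage / fish / smt / genomics.
All randomness derives from one root seed through a documented splitting
scheme (``numpy.random.SeedSequence(root).spawn``, one child per stage, in
the fixed stage order), so re-running an identical config reproduces
byte-identical outputs.  Unknown config keys are rejected; warnings raised
by any stage are counted in the report, never swallowed.  The run report
lists every output file with its sha256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from condensatekit import fish as fish_mod
from condensatekit import genomics, imaging, metaimage, smt, synthdata

__all__ = ["RunConfig", "validate_config", "run", "DEMO_CONFIG"]

STAGE_ORDER = ("synthdata", "imaging", "metaimage", "fish", "smt", "genomics")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RunSection(_Section):
    seed: int = 0
    outdir: str = "runs/demo"
    stages: list[str] = Field(default_factory=lambda: list(STAGE_ORDER))

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        unknown = [s for s in v if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        return v


class SynthSection(_Section):
    n_nuclei: int = Field(8, ge=1)
    foci_mu: float = Field(5.0, ge=0)
    foci_sigma: float = Field(1.5, ge=0)
    partition: float = Field(3.0, ge=1)
    cochannel_enrichment: float = Field(2.0, ge=0)
    snr: float = Field(10.0, gt=0)
    n_spots: int = Field(30, ge=0)
    n_tracks: int = Field(60, ge=1)
    track_length: int = Field(60, ge=2)
    D_true: float = Field(0.5, ge=0)
    n_fragments: int = Field(20_000, ge=1)
    enrichment_fold: float = Field(4.0, ge=0)
    n_hse_enriched: int = Field(10, ge=0)


class ImagingSection(_Section):
    backend: str = "classical"
    pixel_size: float = Field(0.1, gt=0)


class MetaimageSection(_Section):
    window: int = Field(23, ge=3)
    radius: int = Field(3, ge=0)
    randomize_control: bool = True

    @field_validator("window")
    @classmethod
    def _odd(cls, v):
        if v % 2 == 0:
            raise ValueError("window must be odd")
        return v


class FishSection(_Section):
    bin_width: float = Field(100.0, gt=0)
    k_sites: int = Field(2, ge=1)


class SmtSection(_Section):
    max_disp: float = Field(5.0, gt=0)
    min_frames: int = Field(15, ge=0)
    dt: float = Field(0.03, gt=0)
    pixel_size: float = Field(0.1, gt=0)
    fit_lags: int = Field(4, ge=1)


class GenomicsSection(_Section):
    flank: int = Field(300, gt=0)
    window: int = Field(50, gt=0)
    pseudocount: float = Field(1.0, ge=0)


class RunConfig(_Section):
    run: RunSection = RunSection()
    synthdata: SynthSection = SynthSection()
    imaging: ImagingSection = ImagingSection()
    metaimage: MetaimageSection = MetaimageSection()
    fish: FishSection = FishSection()
    smt: SmtSection = SmtSection()
    genomics: GenomicsSection = GenomicsSection()


DEMO_CONFIG = """\
[run]
seed = 1
outdir = "runs/demo"
stages = ["synthdata", "imaging", "metaimage", "fish", "smt", "genomics"]

[synthdata]
n_nuclei = 8
partition = 3.0
cochannel_enrichment = 2.0
snr = 10.0
n_spots = 30
n_tracks = 60
track_length = 60
D_true = 0.5
n_fragments = 20000

[metaimage]
window = 23
radius = 3

[smt]
max_disp = 5.0
min_frames = 15
dt = 0.03
"""


def validate_config(path) -> RunConfig:
    """Parse and range-check a TOML config; raises with an exhaustive error list."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = [f"  {'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()]
        raise ValueError("invalid config:\n" + "\n".join(lines)) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(root_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(len(STAGE_ORDER))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGE_ORDER, children)}


def run(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; returns the run report.

    The report (also written to ``<outdir>/report.json``) records per-stage
    record counts, parameters, seeds, warning counts and a checksum manifest
    of every output file.  Re-running the same config reproduces identical
    checksums.
    """
    outdir = Path(config.run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.run.seed)
    selected = [s for s in STAGE_ORDER if s in config.run.stages]
    state: dict = {}
    report: dict = {"seed": config.run.seed, "stage_seeds": {s: seeds[s] for s in selected},
                    "stages": {}, "manifest": {}}
    files: list[Path] = []

    for stage in selected:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            counts = _STAGE_FUNCS[stage](config, seeds[stage], outdir, state, files)
        report["stages"][stage] = {
            "params": getattr(config, stage).model_dump(),
            "seed": seeds[stage],
            "counts": counts,
            "n_warnings": len(caught),
            "warnings": sorted({str(w.message) for w in caught}),
        }

    for path in files:
        report["manifest"][str(path.relative_to(outdir))] = _sha256(path)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _require(state: dict, key: str, stage: str, needed_by: str):
    if key not in state:
        raise RuntimeError(f"stage {needed_by!r} requires output of stage {stage!r}, "
                           "which did not run")
    return state[key]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_synthdata(config, seed, outdir, state, files):
    p = config.synthdata
    rng_seeds = np.random.SeedSequence(seed).spawn(5)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in rng_seeds]

    image, truth = synthdata.gen_condensate_scene(
        n_nuclei=p.n_nuclei, foci_per_nucleus=(p.foci_mu, p.foci_sigma),
        partition=p.partition, cochannel_enrichment=p.cochannel_enrichment,
        snr=p.snr, seed=sub[0])
    # a foci-free companion scene for the randomized-placement null
    null_image, null_truth = synthdata.gen_condensate_scene(
        n_nuclei=p.n_nuclei, foci_per_nucleus=0, partition=1.0,
        cochannel_enrichment=1.0, snr=p.snr, seed=sub[1])
    paths = synthdata.write_scene(outdir / "scene", image, truth)
    files.extend(Path(v) for v in paths.values())

    fish_img, fish_truth = synthdata.gen_fish_scene(n_spots=p.n_spots, seed=sub[2])
    # confinement box spreads track origins so re-linking the pooled
    # detections recovers distinct molecules
    tracks = synthdata.gen_tracks(
        synthdata.TrackTruth(D_true=p.D_true, n_tracks=p.n_tracks,
                             track_length=p.track_length,
                             box=(0.0, 20.0, 0.0, 20.0)), seed=sub[3])
    lib_truth = synthdata.FragmentLibraryTruth(enrichment_fold=p.enrichment_fold)
    enriched = lib_truth.hse_positions[: p.n_hse_enriched]
    stress_truth = synthdata.FragmentLibraryTruth(
        enrichment_fold=p.enrichment_fold, hse_positions=enriched)
    mock_truth = synthdata.FragmentLibraryTruth(enrichment_fold=1.0)
    stress_frags = synthdata.gen_fragment_library(stress_truth, p.n_fragments, seed=sub[4])
    mock_frags = synthdata.gen_fragment_library(mock_truth, p.n_fragments, seed=sub[4] + 1)

    frag_path = outdir / "fragments_stress.tsv"
    genomics.write_fragments(stress_frags, frag_path)
    mock_path = outdir / "fragments_mock.tsv"
    genomics.write_fragments(mock_frags, mock_path)
    tracks_path = outdir / "tracks.csv"
    tracks.to_csv(tracks_path, index=False)
    files.extend([frag_path, mock_path, tracks_path])

    state.update(scene=(image, truth), null_scene=(null_image, null_truth),
                 fish_scene=(fish_img, fish_truth), tracks=tracks,
                 fragments=(stress_frags, mock_frags),
                 fragment_truth=(stress_truth, mock_truth))
    return {"n_condensates_true": len(truth.condensates),
            "n_spots_true": int((fish_truth["kind"] == "spot").sum()),
            "n_tracks": p.n_tracks,
            "n_fragments": 2 * p.n_fragments}


def _stage_imaging(config, seed, outdir, state, files):
    image, truth = _require(state, "scene", "synthdata", "imaging")
    backend = config.imaging.backend
    nuclei = imaging.segment(image[0], "nuclei", backend=backend)
    condensates = imaging.segment(image[0], "condensates", backend=backend, nuclei=nuclei)
    table = imaging.condensate_table(image[0], nuclei, condensates)
    metrics = imaging.nucleus_metrics(image[0], nuclei, condensates, table)
    t_path = outdir / "condensates.tsv"
    m_path = outdir / "nuclei.tsv"
    table.to_csv(t_path, sep="\t", index=False)
    metrics.to_csv(m_path, sep="\t", index=False)
    files.extend([t_path, m_path])
    state.update(segmentation=(nuclei, condensates), condensate_table=table,
                 nucleus_metrics=metrics)
    return {"n_nuclei": int(nuclei.max()), "n_condensates": len(table),
            "mean_partition": float(metrics["apparent_partition"].mean())}


def _stage_metaimage(config, seed, outdir, state, files):
    image, truth = _require(state, "scene", "synthdata", "metaimage")
    table = _require(state, "condensate_table", "imaging", "metaimage")
    metrics = _require(state, "nucleus_metrics", "imaging", "metaimage")
    p = config.metaimage
    rng = np.random.default_rng(seed)

    ws_self = metaimage.extract_windows(image[0], table, n=p.window)
    ws_co = metaimage.extract_windows(image[1], table, n=p.window)
    meta = metaimage.meta_image(ws_co)
    profile = metaimage.linescan(meta)

    result = {"k": meta.k, "p_value": None, "randomization_seed": seed}
    if p.randomize_control and len(table) >= 2:
        null_image, null_truth = _require(state, "null_scene", "synthdata", "metaimage")
        model = metaimage.fit_placement_model(metrics)
        placed = metaimage.randomize_placement(model, null_truth.nucleus_labels, table, rng)
        if len(placed) >= 2:
            ws_null = metaimage.extract_windows(null_image[1], placed, n=p.window)
            _, _, pval = metaimage.central_enrichment_test(ws_co, ws_null, radius=p.radius)
            result["p_value"] = pval

    meta_path = outdir / "metaimage.tsv"
    np.savetxt(meta_path, meta.mean, delimiter="\t")
    prof_path = outdir / "linescan.tsv"
    np.savetxt(prof_path, profile, delimiter="\t")
    test_path = outdir / "enrichment_test.json"
    test_path.write_text(json.dumps(result, indent=2, sort_keys=True))
    files.extend([meta_path, prof_path, test_path])
    state.update(metaimage=meta, linescan=profile, enrichment_test=result)
    return {"k_windows": meta.k, "p_value": result["p_value"]}


def _stage_fish(config, seed, outdir, state, files):
    fish_img, fish_truth = _require(state, "fish_scene", "synthdata", "fish")
    p = config.fish
    curve = fish_mod.threshold_scan(fish_img, bin_width=p.bin_width)
    knee = fish_mod.knee_threshold(curve)
    foci, labels = fish_mod.call_foci(fish_img, knee.threshold)
    sites = fish_mod.call_transcription_sites(foci, k=p.k_sites)
    foci = foci.copy()
    foci["is_ts"] = foci["focus_id"].isin(sites["focus_id"])
    f_path = outdir / "fish_foci.tsv"
    foci.to_csv(f_path, sep="\t", index=False)
    files.append(f_path)
    state.update(fish_result=(curve, knee, foci, sites, labels))
    return {"knee_threshold": knee.threshold, "knee_found": knee.found,
            "n_foci": len(foci), "n_ts": len(sites)}


def _stage_smt(config, seed, outdir, state, files):
    tracks_truth = _require(state, "tracks", "synthdata", "smt")
    p = config.smt
    detections = tracks_truth[["frame", "x", "y"]].copy()
    detections.attrs["dt"] = p.dt
    linked = smt.link_detections(detections, max_disp=p.max_disp * p.pixel_size)
    kept = smt.filter_tracks(linked, min_frames=p.min_frames)
    estimates = smt.estimate_D_per_track(kept, dt=p.dt, fit_lags=p.fit_lags)
    d_path = outdir / "diffusion.tsv"
    estimates.to_csv(d_path, sep="\t", index=False)
    files.append(d_path)
    state.update(diffusion=estimates)
    return {"n_tracks_linked": int(linked["track_id"].nunique()),
            "n_tracks_kept": int(kept["track_id"].nunique()),
            "median_D": float(estimates["D"].median()) if len(estimates) else None}


def _stage_genomics(config, seed, outdir, state, files):
    stress_frags, mock_frags = _require(state, "fragments", "synthdata", "genomics")
    stress_truth, mock_truth = _require(state, "fragment_truth", "synthdata", "genomics")
    p = config.genomics

    result = {}
    tracks = {}
    for name, frags in (("stress", stress_frags), ("mock", mock_frags)):
        spike = int((frags["source"] == "spike").sum())
        factor = genomics.spike_in_factor(spike, len(frags))
        target = frags[frags["source"] == "target"]
        track = genomics.coverage(
            target, scale=factor,
            chrom_sizes={stress_truth.chrom: stress_truth.genome_length})
        tracks[name] = track
        result[f"{name}_spike_factor"] = factor
        bg_path = outdir / f"coverage_{name}.bedgraph"
        genomics.write_bedgraph(track, bg_path)
        files.append(bg_path)

    hse_set = pd.DataFrame({
        "chrom": stress_truth.chrom,
        "start": [h - 10 for h in mock_truth.hse_positions],
        "end": [h + 10 for h in mock_truth.hse_positions],
        "name": [f"HSE_{i}" for i in range(len(mock_truth.hse_positions))],
        "strand": ".",
    })
    profile = genomics.metaprofile(tracks["stress"], hse_set, flank=p.flank)
    calls = genomics.hse_classify(tracks["stress"], tracks["mock"], hse_set,
                                  window=p.window, pseudocount=p.pseudocount)
    prof_path = outdir / "hse_metaprofile.tsv"
    pd.DataFrame({"position": profile.positions, "signal": profile.values}).to_csv(
        prof_path, sep="\t", index=False)
    calls_path = outdir / "hse_log2fc.tsv"
    calls.to_csv(calls_path, sep="\t", index=False)
    files.extend([prof_path, calls_path])
    state.update(coverage=tracks, hse_calls=calls)
    result.update({"n_hse": len(calls), "n_upregulated": int(calls["upregulated"].sum())})
    return result


_STAGE_FUNCS = {
    "synthdata": _stage_synthdata,
    "imaging": _stage_imaging,
    "metaimage": _stage_metaimage,
    "fish": _stage_fish,
    "smt": _stage_smt,
    "genomics": _stage_genomics,
}
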