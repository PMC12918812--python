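# condensatekit

Quantitative analysis of stress-induced transcription-factor condensates.

Stress-responsive transcription factors such as HSF1 form nuclear
condensates — bright foci over a diffuse nucleoplasmic pool — whose
composition and dynamics decide whether they act as transcription hubs or
as sequestration sites. `condensatekit` packages the analyses that
characterize them, for microscopists and genomicists who have segmented
images, single-molecule tracking movies, smFISH stacks, or CUT&RUN /
nascent-RNA libraries and want the published quantities computed
reproducibly:

* **Morphometrics** (`condensatekit.imaging`) — pluggable nucleus/condensate
  segmentation (classical scikit-image default; any callable backend,
  including deep-learning segmenters, can be registered) and per-object
  statistics: foci count, area, eccentricity
  e = √(1 − (minor/major)²), nuclear MFI, and the apparent partition
  *P* = ⟨I⟩_condensate / ⟨I⟩_nucleoplasm.
* **Meta-image co-enrichment** (`condensatekit.metaimage`) — n × n windows
  around each condensate, their pixel-wise mean (meta-image),
  min-subtracted diagonal line scans, an unpaired t-test on central ±3 px
  box sums against a randomized-placement null (control condensates
  re-placed on foci-free nuclei, counts ~ fitted Normal), and
  Kolmogorov–Smirnov area matching by importance subsampling.
* **smFISH** (`condensatekit.fish`) — iterative threshold scans (regional
  maxima counted every 100 intensity units), knee-point threshold selection
  (distance-to-chord), foci as connected components with total fluorescent
  intensity (TFI), top-2 TFI transcription-site calls, and cross-channel
  TFI of intron-derived masks on the exon channel.
* **Single-molecule tracking** (`condensatekit.smt`) — nearest-neighbour
  linking (max displacement 5 px, no gap closing), strict >15-frame
  filtering, condensate-ROI assignment, time-averaged MSD and per-track
  diffusion coefficients from MSD = 4·D·t (origin fit, lags 1–4).
* **Genomics** (`condensatekit.genomics`) — fragment-length classes
  (≤120 bp / ≥150 bp), spike-in factors 1/(spike/total), per-base scaled
  coverage, strand-aware metaprofiles around HSEs or TSSs, log2FC-based
  HSE classification against mock, and per-locus minimum-background
  subtraction; BED/bedGraph/TSV I/O.
* **Synthetic data** (`condensatekit.synthdata`) — ground-truthed
  generators for every input modality (condensate scenes, smFISH images,
  Brownian tracks, fragment libraries with spike-ins), so the whole
  pipeline is testable with no downloads.

## Worked example

Run the end-to-end demo pipeline on synthetic data (a scene with planted
partition 3 and 2-fold co-channel enrichment):

```sh
$ cat demo.toml
[run]
seed = 1
outdir = "demo_out"
stages = ["synthdata", "imaging", "metaimage", "fish", "smt", "genomics"]

[synthdata]
partition = 3.0
cochannel_enrichment = 2.0

$ condensatekit run --config demo.toml
{
  "synthdata": { "n_condensates_true": 22, "n_spots_true": 30,
                 "n_tracks": 60, "n_fragments": 40000 },
  "imaging":   { "n_nuclei": 8, "n_condensates": 22,
                 "mean_partition": 2.8115426884967114 },
  "metaimage": { "k_windows": 22, "p_value": 9.61559885580719e-38 },
  "fish":      { "knee_threshold": 300.0, "knee_found": true,
                 "n_foci": 31, "n_ts": 2 },
  "smt":       { "n_tracks_linked": 137, "n_tracks_kept": 86,
                 "median_D": 0.4361457684968971 },
  "genomics":  { "stress_spike_factor": 20.181634712411707,
                 "mock_spike_factor": 19.880715705765407,
                 "n_hse": 20, "n_upregulated": 11 }
}
```

Reading the numbers: segmentation found all 8 nuclei and all 22 planted
condensates, and the mean apparent partition (2.81) recovers the planted 3.0
to within 7 % — segmentation masks capture the bright core of each
diffraction-blurred focus, so a mild underestimate is expected. The
meta-image t-test rejects the randomized-placement null decisively
(p ≈ 1e-37) because a 2-fold co-enrichment was planted (windows over
condensates versus control condensates randomly re-placed on foci-free
nuclei). The smFISH knee
landed at 300 intensity units, separating all 30 planted spots plus the two
transcription sites (one pair of spots merged into a single component,
hence 31 foci; the two brightest-TFI foci are the planted TS). Re-linking
the pooled detections breaks tracks whenever a Brownian step exceeds the
5 px search radius, so 60 simulated molecules yield 137 track fragments, 86
of them longer than 15 frames, with median D̂ = 0.44 µm²/s against a planted
0.5 (the max-displacement cut preferentially discards large steps — a known,
documented bias of bounded-search linking). The two fragment libraries get
spike-in factors near 20 (5 % spike-in), and 11 of 20 HSEs are called
upregulated at this depth against the 10 actually planted — one background
locus crossed the strict log2FC > 0 line at the demo's 20,000-fragment
depth; at the benchmark depth of 50,000 the call is exact.

Outputs land in `demo_out/` as TIFF label maps, TSV tables, bedGraph tracks
and a `report.json` whose sha256 manifest is byte-identical across re-runs
with the same config.

Library use mirrors the CLI, e.g.:

```python
from condensatekit import synthdata, imaging, metaimage

image, truth = synthdata.gen_condensate_scene(partition=3.0, snr=10, seed=7)
nuclei = imaging.segment(image[0], "nuclei")
condensates = imaging.segment(image[0], "condensates", nuclei=nuclei)
table = imaging.condensate_table(image[0], nuclei, condensates)
metrics = imaging.nucleus_metrics(image[0], nuclei, condensates, table)
ws = metaimage.extract_windows(image[1], table, n=23)
profile = metaimage.linescan(metaimage.meta_image(ws))
```

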