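# Methods

`condensatekit` implements the quantitative analyses used to characterize
nuclear condensates of stress-responsive transcription factors and their
functional output: image-side morphometrics and co-enrichment statistics,
smFISH foci/transcription-site calling, intra-condensate single-molecule
diffusion, and spike-in-normalized genomic occupancy. Every stage is
exercised end-to-end on a ground-truthed synthetic-data generator, so all
quantitative claims in the test suite are recomputed from scratch against a
known truth.

## Condensate scenes and morphometrics

Synthetic scenes render non-overlapping elliptical nuclei (semi-axes ~15–27
px, rejection-sampled) on a dim extranuclear background (20 counts) with a
flat nucleoplasm (200 counts). Condensates are Gaussian-blurred discs
(radius 3–6 px, blur σ = 1 px) whose additive amplitude is normalized so
that the mean over each condensate's truth mask is exactly
(partition − 1) × nucleoplasm; the truth mask is the 5 %-of-peak contour of
the blurred footprint, so nearly all rendered mass lies inside the mask and
the nucleoplasm stays clean. The *apparent partition* — mean intensity over
a nucleus's condensate pixels divided by the mean over its non-condensate
nuclear pixels — therefore recovers the requested value directly from the
truth masks. A second channel carries co-imaging signal at a configurable
enrichment ratio over the same masks (1 = flat).

Noise is Poisson shot noise plus Gaussian read noise; `snr` is defined per
channel as (planted contrast in that channel) / noise SD, with the
nucleoplasm mean substituted for the contrast in the flat degenerate cases
(partition 1, enrichment 1). Sizing each channel's noise from its own
contrast means two scenes that differ only in the other channel share
identical noise statistics — which is what keeps the two groups of the
randomized-placement null exchangeable. The read component is sized so the
total nucleoplasm variance hits the target.

Segmentation is a pluggable backend registry (any callable
`image -> LabelMap`, which is where a deep-learning segmenter would plug
in). The shipped classical default:

* **nuclei** — Gaussian smooth (σ = 2) → three-class Otsu taking the lowest
  threshold (robust to bright foci dragging a two-class threshold into the
  nucleoplasm) → 4-connected hole fill → distance-transform watershed to
  split touching nuclei.
* **condensates** — Gaussian smooth (σ = 1) → per-nucleus robust hysteresis
  threshold: detection at median + 5·(1.4826·MAD), extension down to
  median + 2·(1.4826·MAD), 8-connected components, minimum area 5 px.
  Hysteresis captures the dim diffraction rim without admitting isolated
  noise; because the noise SD scales with the planted contrast under the
  `snr` definition, the captured contour sits at a partition-independent
  fraction of the amplitude, keeping the segmentation-based partition
  estimate within ~10 % across partitions 2–5.

Declared conventions (the upstream protocols leave them open): nuclear MFI
is the plain mean over the full nuclear mask, condensate pixels included; a
nucleus with zero called condensates has partition 1.0 by convention;
eccentricity is that of the ellipse with matching second central moments.
The standard pre-segmentation crop pads each nucleus bounding box to
256 × 256 and rescales ×2 bilinearly (512 × 512 out).

## Meta-images, the randomized-placement null, and area matching

For each condensate, an n × n window (default n = 23, covering a ~2.7 µm
zoom-in at ~0.12 µm/px) is cut per channel around the rounded centroid;
edge-touching windows are zero-padded and flagged. The meta-image is the
pixel-wise mean; the line scan is the main diagonal minus its minimum.

Co-enrichment is tested on per-window sums of co-channel signal within ±3 px
of the window center (a 7 × 7 box — the literal reading of ± in both axes),
compared between groups by a two-sided unpaired Student t-test (pooled
variance; Welch behind a flag). The null group re-places condensates sampled
from a control condition onto foci-free nuclei: per-nucleus counts are drawn
from a normal distribution fitted to the control (rounded, clipped at 0) and
centroids land uniformly on the nucleus mask eroded by each condensate's
equivalent radius — the same own-radius margin with which real condensates
sit inside nuclei, so the window-edge composition of the two groups matches
and the test calibrates (measured type-I error ≈ 0.04–0.05 at α = 0.05 over
1000 repeats). Per-window sums are pooled across cells; per-cell
aggregation is exposed as an option upstream of the test.

Area matching to a reference condition (auto = lowest mean area) assigns
each source condensate an importance weight w(a) = density_ref(a) /
density_src(a) on shared log-spaced bins (32 by default; w = 0 where the
reference has no mass). Per iteration, 5 % of the source is removed from the
over-represented (w < 1) bins, allocated proportionally to each bin's excess
over the reference shape so no bin is pushed below it, with uniformly random
victims within a bin; densities are recomputed each round and the loop stops
when the two-sample KS p-value reaches 0.05, the retained fraction falls
below 0.15, or after 50 iterations. A strict "drop the globally
lowest-weight items" rule was tried first and cannot converge — it truncates
whole bins and leaves the interior shape mismatched — whereas the
excess-proportional allocation is a stochastic iterative proportional fit
that reshapes the histogram to the reference (on a +50 % shifted lognormal:
KS p ≈ 0.06–0.09, matched mean within ~6 %). Disjoint area supports yield an
empty result with an explicit failure row in the report.

## smFISH foci and transcription sites

Per nucleus, regional maxima (8-connected plateaus) are counted at every
threshold from 0 to the image maximum in steps of 100 intensity units.
Counting runs on a 1-px-smoothed copy by default so single-pixel noise
maxima do not dominate the low-threshold end (a raw-image option is
retained); total fluorescent intensity (TFI) is always summed on raw
pixels. The optimal threshold is the knee of the count-vs-threshold curve:
after min-max normalization of both axes, the threshold maximizing the
signed perpendicular distance below the endpoint chord (the canonical
distance-to-chord construction for a convex decreasing curve, sensitivity
1). An essentially linear curve (max distance < 1 % of the diagonal)
returns the midpoint with a no-knee flag.

Foci are 8-connected components above the knee, measured on raw pixels with
intensity-weighted centroids (robust when a bright site shares a component
with dim neighbours). Transcription sites are the top-2 foci by TFI, ties
broken by larger area then lower label id; fewer than k foci returns all
with a short-count flag. Cross-channel TFI evaluates the intron-derived
focus masks on the exon channel.

## Single-molecule tracking

Brownian tracks are simulated with per-axis step SD √(2·D·dt), reflecting
walls if confined, plus independent localization noise on the reported
positions; the frame interval defaults to 30 ms. Detections are linked
frame-to-frame by greedy mutual-nearest assignment (globally closest
admissible pair first), rejecting links beyond 5 px and never closing gaps;
detections are canonically sorted within frames so the result is invariant
to input row order, and a full linear-assignment solve is available behind
`method="lap"` (the two coincide at single-molecule sparsity). Tracks
*strictly longer* than 15 frames survive filtering. ROI membership requires
≥ 50 % of localizations inside a condensate bounding box (configurable);
overlapping boxes resolve by majority. Condensate boxes are traced from the
condensate channel by watershedding a Laplacian-of-Gaussian response from
blob-center seeds, splitting adjacent condensates along the intensity
ridge between them.

The time-averaged MSD, msd(k·Δt) = meanᵢ |r(i+k) − r(i)|², is fitted through
the origin over lags 1–4 (the standard low-bias short-lag choice) with
MSD = 4·D·t; D = slope/4, negative slopes clipped to 0 and flagged. D is
estimated per track and pooled. On noiseless ensembles (500 tracks, length
100) the median D̂ is within ~4 % for D ∈ {0.05, 0.5, 5} µm²/s; localization
noise adds a positive offset 4σ²/(4·dt·⟨k⟩) that is most visible at the
smallest D.

## Fragment libraries, spike-in normalization and HSE classification

The synthetic genome is a single 20 kb chromosome with 20 heat-shock-element
(HSE) anchors ~1 kb apart. This desk-scale choice is deliberate: at 50,000
fragments it gives per-base depths comparable to a real CUT&RUN library at
called peaks, so window means at HSEs have low sampling noise. Fragment
midpoints are uniform except within a 200 bp capture window of an enriched
HSE, where the density is exactly `enrichment_fold`-fold the background;
the total count is fixed (fixed sequencing depth), so enrichment
redistributes mass and non-enriched loci in an enriched library sit
slightly below the mock background. Lengths come from a two-mode normal
mixture (80 ± 10 bp factor footprints, 180 ± 15 bp nucleosomal); a Bernoulli
fraction (default 5 %) of fragments is drawn uniformly from a separate
spike-in chromosome.

Coverage is the per-base count of overlapping full fragment spans (bin 1)
times the spike-in factor 1/(spike reads / total reads); each sample is
scaled by its own factor. Coverage mass equals scale × Σ fragment lengths
exactly. Fragment classes split at ≤ 120 bp (factor) and ≥ 150 bp
(nucleosome); the printed inequalities leave 121–149 bp unassigned, and that
gap is preserved as a separate middle class rather than closed.

Metaprofiles average signal at anchor ± flank per locus (anchor = interval
midpoint for HSEs, annotated TSS for genes, default flank 2 kb for
nascent-RNA profiles; minus-strand loci reversed), then across replicates
with equal weight. HSE regulation is the log2 fold change of mean signal
within ±50 bp between stress and mock, with a pseudocount of 1.0 on the
scaled signal to guard zero-signal loci; upregulated iff log2FC > 0
(strict). Under the null the strict threshold splits ~50/50, and with 10 of
20 HSEs planted at 4-fold the split is exact with planted log2FC ≥ ~1.4
versus background ≤ ~−0.1. Per-locus plotting background is the minimum
signal within ±1 kb of the anchor.

## Pipeline

A single TOML config with per-stage sections drives synthdata → imaging →
metaimage / fish / smt / genomics. All randomness descends from one root
seed via `numpy.random.SeedSequence.spawn` in fixed stage order; re-running
an identical config reproduces byte-identical outputs, verified by sha256
checksums in the run report. Unknown keys and out-of-range values are
rejected with the offending field named; stage warnings are counted in the
report, never swallowed.

## What the synthetic data does and does not show

The generator reproduces the statistical structure each stage assumes —
partition/enrichment ratios, Brownian displacement statistics,
diffraction-limited spots, fragment-length mixtures, spike-in proportions —
but not optics (no PSF model, no 3D rendering; a maximum-intensity
projection equivalent 2D scene suffices), no cell-to-cell intensity
variability, no chromatin-driven coverage bias, and no segmentation-model
domain shift. Passing tests therefore demonstrate correctness of the
estimators and statistics under their stated models, not robustness to
every artifact of real microscopes or libraries. The pixel pitch (0.1
µm/px default) is a configuration parameter; SMT unit conversions require
it.

## Problem sizes

The shipped experiments use 50-nuclei scenes for partition recovery, 1000
repeats for null calibration, 100 repeats at 200 condensates/group for
power, 500 tracks × 100 frames per diffusion condition, 20 seeds for smFISH
recall/precision, and 50,000-fragment libraries — sizes at which every
sampling-based claim has comfortable margin while a full run of the
benchmark suite completes in a few minutes on one CPU.
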