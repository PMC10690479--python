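# Methods

This note documents the models behind each `cargoquant` stage, the
parameters that matter (with defaults and why), what the synthetic data
emulate and do not, and the numerical choices made where the design was
genuinely open.

## Coordinate and unit conventions

`x` is the image column, `y` the row, origin at the top-left pixel;
subpixel positions are real numbers at pixel centers. Physical conversions
use `pixel_size_nm` (default 110 nm/px, typical of a 60–100× spinning-disk
setup) and `frame_interval_s` (default 0.057 s, the frame time of a camera
streaming at ≈17.5 Hz). Both are configurable everywhere.

## Synthetic data

**Fixed-cell scenes.** Nuclei are disks (rejection-sampled to avoid
overlap; placement failure after a bounded number of tries raises an
error naming the constraint). Puncta are isotropic 2D Gaussians of PSF
width `puncta_sigma_px` (default 1.3 px ≈ 143 nm, a realistic
diffraction-limited width at 110 nm/px), rendered by integrating the
Gaussian over each pixel area rather than point-sampling it, so the sum
over a spot equals its nominal photon count exactly — the quantity the
downstream integral-intensity readout estimates. Puncta scatter around
the nucleus centroid with standard deviation `dispersion_px`. Noise is
Poisson (photon) or additive Gaussian; noise-free renders are exact, and
the per-pixel mean of Poisson renders equals the noise-free image.

**Motion.** Trajectories are generated in nm: `stationary`; `diffusive`
with per-axis step variance 2DΔt; `directed` advancing vΔt along a unit
direction; and `run_and_pause`, a three-state machine (apical run, basal
run, stationary pause) with exponential dwell times and runs at
`v_nm_per_s` along ±axis (apical = −y by default, i.e. toward the image
top). Defaults (run speed 500 nm/s, dwell means 6/2/2 s giving a nominal
60/20/20 split of trajectory time, 50 × 50 µm box) emulate sustained
bidirectional cargo transport with runs of a few µm. Boundaries reflect
for diffusive motion; a *run* that reaches the boundary instead ends in a
pause there, because a particle bouncing against the cortex while still
labelled "running" would make the ground-truth labels physically
meaningless. What the generator does **not** model: 3D motion and focus
loss, motor-state kinetics beyond exponential dwells, optical aberrations,
photobleaching, or vignetting — so passing tests demonstrate estimator
correctness under the stated motion models, not robustness to every
artefact of real movies.

**Proteomics.** Per-protein base log2 abundance ~ N(25, 2²) (typical
iBAQ-scale values), replicate noise sd 0.3–0.5 log2 units, `n_spiked`
proteins raised in the bait group by `spike_log2_effect`. Dropout is
missing-not-at-random: the missing probability falls logistically with
log2 intensity, centred 1.5 sd below the mean — emulating
low-abundance-biased missingness in label-free data. Peptide counts are
1 + Poisson(6).

## Segmentation

The nucleus chain is median filter (radius 2 px) → rolling-ball
background subtraction (radius 50 px, grayscale morphology with a ball
element — the standard meaning of that filter) → threshold → optional
distance-transform watershed → 8-connected components, relabelled
contiguously; components under `min_area` (25 px) are treated as noise
excursions and dropped, and regions touching the image border are
discarded to avoid scoring incomplete cells.

**PFA threshold.** The "probability of false alarm" threshold
is calibrated against a robust Gaussian background model: threshold =
median + z(1 − pfa)·(1.4826·MAD), both statistics taken on the filtered
image. Median/MAD tolerate the bright objects that would inflate a mean/sd
fit. A zero-variance image has no definable threshold and raises
"degenerate background". On pure noise the realized above-threshold pixel
fraction matches the nominal pfa within binomial error (tested at
10⁻², 10⁻³, 10⁻⁴).

**Cell partition.** Each foreground pixel is assigned to the nucleus
minimizing the Euclidean distance to that nucleus's pixel set (pixels
inside a nucleus have distance ≤ 0 and map to it — the signed-EDT
construction). Ties break toward the lowest nucleus label so outputs are
deterministic; the assignment is verified against an exhaustive
nearest-nucleus search on small instances. The foreground itself is the
Gaussian-smoothed max projection over channels thresholded at a quantile
of its own distribution (`≥` rather than `>`, so the mask tends to
all-ones in the quantile → 0 limit); the construction is invariant to
adding a constant to the image.

**Puncta.** Connected components of −LoG(image)·σ² above a threshold,
area ≥ `min_area` (5 px, the conventional small-particle cutoff). Because
the chain's usual description leaves the threshold's nature open, both an
absolute mode and a noise-scaled mode (median + k·MAD of the LoG response,
k = 5) are provided; LoG kills constant offsets, so detection is
offset-invariant. A raw-intensity threshold variant
(`segment_by_intensity_threshold`) covers the particle-count path.

## Puncta statistics

The spread statistic uses the intensity-weighted centroid as reference —
both the raw sum Σwᵢ‖pᵢ − c‖² (the primary, comparison-ready value) and
the normalized form (spread / total intensity, px²) are reported, since
the former scales with expression level and the latter is a pure
dispersion length². Fixed colocalization counts a channel-1 punctum as
overlapping when its pixel set intersects any channel-2 punctum, reported
as % of channel-1 puncta per cell — deliberately asymmetric, and undefined
(missing, not 0) for cells without channel-1 puncta. Zone quantification
assigns each punctum to the half-open rectangle containing its centroid
(boundary puncta count once) and validates each rectangle's physical area
(default 300 µm²) to within one pixel's area.

## Tracking and motility

**Detection.** Candidate spots are 3×3 local maxima whose raw peak value
exceeds the robust background threshold median + z(1 − pfa)·σ̂ — "pfa" is
per pixel, so no user intensity threshold exists. Candidates are refined
by least-squares symmetric 2D Gaussian fits (amplitude, x, y, σ, offset);
non-convergent or out-of-window fits are dropped and counted in a
diagnostics record, and fits converging within 1 px of a brighter
detection are merged. Consequently the final spot count on pure noise sits
at or below pixels × pfa: the gate realizes the nominal rate and the fit
stage can only reject further (non-blob excursions). Integrated intensity
is the area under the fit, 2πAσ².

**Linking.** Per consecutive frame pair, the assignment minimizing total
squared displacement (Hungarian algorithm on an augmented cost matrix)
with links beyond `max_disp` (5 px) forbidden; `memory` > 0 keeps
unmatched tracks eligible for re-linking across that many missed frames.
Tracks under 10 timepoints are discarded before MSD analysis — short
tracks make MSD estimates unacceptably noisy — and an optional ROI polygon
drops tracks whose mean position falls outside cells.

**MSD.** Per track, MSD(kΔt) averages ‖p(i+k) − p(i)‖² over *all* ordered
pairs; the pair count is retained as the weight. The across-track mean
weights each track's value at a delay by its pair count. Delays default to
the first 25% of track duration for slope fitting, limiting the variance
blow-up at long delays; D is slope/4 over the first 10 delays.

**Live colocalization.** Per timepoint, % of channel-1 tracks present
with a channel-2 track-member spot within 300 nm (≈ the optical
resolution), averaged over the first 50 timepoints to damp transient
encounters. The denominator counts tracks *present at that timepoint*;
movies with no channel-1 track in the window report missing. On the
dual-channel bead control the chain reports 100% by construction — the
validation the package's acceptance script recomputes.

**Run classification.** Axial velocity (projection on the apical axis) is
smoothed with a centred moving average (`smooth_window` = 3 frames;
shorter tracks are classified unsmoothed and flagged), then classified at
±`v_min` (100 nm/s — comfortably between noise and the ~500 nm/s run
speed); contiguous same-class steps merge into segments, and directed
segments whose net axial length falls below `min_run_length` (500 nm) are
reclassified as stationary, so the inclusion threshold can only reduce
run percentages. These three thresholds are not asserted as anyone's
published values; they are exposed in configuration and echoed into
output metadata. On simulated run-and-pause data the classifier recovers
the ground-truth % apical within ~1 point (systematically slightly low,
from transition smearing and the min-run rule).

## Enrichment screen

Filtering keeps proteins with ≥2 peptides and ≥3 quantification events in
at least one group and drops reverse/contaminant-flagged rows.
Normalization divides each sample by its median over complete-case
proteins only (so dropout patterns cannot bias it); all sample medians
become 1, which makes the pipeline exactly invariant to per-sample
multiplicative scaling — a data-dependent global rescale would break that
exactness, so none is applied. Imputation draws missing log2 values from
N(mean − 1.8·sd, (0.3·sd)²) per sample — the de-facto defaults of the
standard label-free workflow, exposed in configuration since the
procedure itself only fixes "a normal distribution per sample".

The test statistic is Welch's t with S0 = 0.1 added to the denominator,
damping tiny-variance/small-effect proteins; the log2 fold change is the
difference of group medians (a mean mode exists for sensitivity checks).
With s0 = 0 the statistic equals the textbook Welch t to 1e-10.

**Permutation FDR.** For each threshold on |t|, FDR = (mean permuted
count ≥ threshold)/(observed count ≥ threshold); a protein's q is the
minimum FDR over thresholds at or below its own |t|, monotonized and
capped at 1. Label assignments equivalent to the observed split — the
identity and, for two groups, the whole-group swap — leave every
protein's |t| unchanged and are excluded from the null ensemble: at
3 vs 3 they would otherwise impose a hard floor of 2/20 on every FDR
estimate and nothing could ever reach q < 0.05 from triplicates. The
remaining 18 informative assignments are enumerated exhaustively (and
re-weighted, rather than sampling 250 with replacement); with more
replicates, up to `n_perm` (250) assignments are sampled uniformly
without replacement. Enrichment requires log2FC strictly greater than
log2(10) = 3.322 **and** q strictly below 0.05. Multiple testing is
permutation-FDR only; no Benjamini–Hochberg fallback is applied.

## Pipeline runs and provenance

`run_pipeline` executes a YAML-configured stage sequence
(fixed-scene / bead-coloc / motility / enrichment), rejects unknown
configuration keys, aborts naming the failing stage, and writes a
`provenance.json` (config, SHA-256 config hash, seed, package version)
next to the outputs; re-running a config reproduces all outputs
byte-for-byte because every stochastic stage is seeded.

## Problem sizes in the test-suite and acceptance runs

The shipped tests exercise the statistics at sizes chosen to make their
sampling error small relative to the asserted tolerances while keeping
the suite quick: 500 tracks × 100 frames for the diffusive 4D slope
(10% tolerance), 1,000 proteins × 20 seeds for null FDR calibration and
spike-in recovery, 60 particles × 400 frames for run-classification
recovery, and 10 beads × 60 frames for the colocalization control.

## Known limitations

- Segmentation is 2D only; the learned-segmentation path for nuclei and
  deconvolution are out of scope.
- The Gaussian-fit detector assumes isotropic PSFs and resolvable spots;
  heavily overlapping puncta merge (the fixed-scene example loses ~1 of
  60 puncta this way).
- Linking is nearest-neighbour optimal per frame pair, not a multi-frame
  global optimum; dense, fast fields can swap identities.
- The permutation null at 3 vs 3 rests on 18 informative relabelings;
  q-values are correspondingly granular near 0.
- Run classification reports net axial displacement per segment; purely
  lateral motion is counted as stationary by design.
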