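# Methods

This note documents the models, parameter choices and numerical conventions
behind each pipeline, what the synthetic generators do and do not emulate,
and the limitations a user should know about.

## Image conventions

All images are handled as floating point on a [0, 1] scale; integer TIFFs
are divided by their dtype maximum on read (camera bit depth is rarely
recorded in the file, so this is a convention, not metadata). The H-minima
depth (H = 0.05) and the 2% ΔF/F₀ amplitude threshold only make sense on a
normalized scale, which motivates the convention. Axis order is
`(z|t, y, x)`, indices 0-based, crop intervals half-open. Calibration
(pixel/voxel size in µm, frame rate in Hz) comes from a YAML sidecar or
explicit arguments — never guessed from TIFF tags, because the acquisition
pixel size depends on objective and binning (0.065 µm/px at 100×,
0.108 µm/px at 60× for the unbinned camera; ~0.133 µm/px for the binned
133 µm-wide fields). Pixel size is therefore a required input of every
physical measurement.

## 2D marker quantification

The coverage chain is: mean z-projection (default 20 planes centered on the
stack midpoint) → 5×5 median filter → scalar background subtraction →
H-minima transform (H = 0.05) → CLAHE → Otsu binarization → area fraction
and integrated density.

Choices that were genuinely open:

* **Background level.** A histogram-shape estimate: locate the mode of the
  256-bin intensity histogram (the background peak) and walk toward higher
  intensities until the bin count first drops below half the mode count;
  that bin center is the background. The triangle threshold is available as
  an alternative (`background_method="triangle"`). A field that is entirely
  background (flat after subtraction) maps to all zeros.
* **"Median filtering (sigma = 5 pixels)".** Median filters have a window,
  not a sigma; implemented as a 5×5 window.
* **CLAHE parameters** are not standardized anywhere: clip limit 0.01,
  64 px tiles, 256 bins, exposed in the config.
* **Integrated density** is summed on the *raw* image under the final mask.
  CLAHE destroys intensity linearity, and integrated signal density is by
  convention a sum of raw intensities.
* **Otsu on a constant image** returns an empty foreground with a warning
  instead of raising, so one degenerate field cannot abort a batch; ties at
  the threshold go to background (foreground is strictly above).
* **Colocalization** is mask overlap (pixelwise AND of the two binarized
  channels), reported with the same area-fraction/integrated-density
  metrics. Intensity-correlation coefficients (Manders, Pearson) are out of
  scope; the mask-overlap reading matches an area/ISD-style quantification.
* **Mitochondria morphometry** replaces interactive freehand tracing with
  an explicit `path_mask` input (any binary TIFF). Objects are 8-connected
  components of the marker mask inside the path; length is the region's
  major-axis length in µm with a one-pixel floor, and per-neurite means are
  reported.

## 3D neurite morphometry

The chain is: optional Richardson–Lucy deconvolution (Gaussian PSF,
default off — the morphometry must stand alone without commercial
deconvolution) → 3D Gaussian smoothing (σ = 3 px) → local background
subtraction → single-scale Frangi vesselness (scale 10 px, α = β = 0.5,
γ = half the maximum Hessian norm) → Otsu binarization → removal of
sub-resolution objects → 3D morphological thinning → connected-component
fragment statistics (26-connectivity, anisotropic step lengths).

Numerical choices and their reasons:

* **Background subtraction** defaults to subtracting a wide Gaussian blur
  (σ = 2× the Frangi scale). A rolling-ball estimate is selectable, but its
  background has sharp creases wherever the ball cannot follow the surface,
  and the Hessian amplifies those creases into spurious ridges that survive
  Otsu — on phantoms this merged well-separated tubes into one component.
  A smooth background estimator cannot inject ridges.
* **Sub-resolution cleanup.** Single-scale vesselness at scale σ produces
  side-lobe responses near tube ends at 25–45% of the peak, which survive
  Otsu as small separate objects. The segmented mask of a true tube is
  about one filter scale thick, so the smallest resolvable fragment — a
  tube at least σ long — occupies ≈ π·(σ·dx)³ (≈ 7.4 µm³ at 0.133 µm/px).
  Binary objects below that volume are removed before thinning. This is the
  only pruning applied by default; skeleton-level `min_voxels` pruning
  exists but is off (single-voxel fragments are kept with length 0).
  Skeleton-size filtering cannot replace the mask-volume rule: a genuine
  fat tube can thin to an 11-voxel skeleton while an artifact thins to 13.
* **Thinning and homotopy.** `skimage` 3D thinning can erode a very small
  object away entirely; one voxel (the component's median coordinate) is
  restored per lost component so the skeleton always preserves the mask's
  component count.
* **Fragment length** is the sum over adjacent skeleton-voxel pairs
  (26-neighborhood, each pair once) of the anisotropic Euclidean step
  √((dz·vz)² + (dy·vy)² + (dx·vx)²) — the total curvilinear extent of the
  component. On thinned skeletons this agrees with the minimum-spanning-tree
  geodesic length to within a percent.
* **Known biases.** PSF blur extends tube ends while thinning retracts
  them; on phantoms the net mean-length bias is a few percent, but a single
  short fragment can be off by ±20%. Fragment counts are exact on noise-free
  phantoms and within ±10% at SNR 10 (n = 1–20 fragments per field).

## Calcium-imaging analysis

* **Activity map.** Each frame-to-frame difference image is low-pass
  filtered in the 2D Fourier domain (Gaussian, cutoff 0.1 cycles/px) and
  its squared magnitude is accumulated over time. Filtering *before* the
  magnitude keeps sub-noise fluorescence steps in the linear regime — a
  coherent cell-sized step survives spatial averaging while per-pixel noise
  cancels — and squaring emphasizes the large coherent steps of genuine
  transients. With magnitudes accumulated first (the other reading of
  "cumulative difference … filtered"), the |·| nonlinearity suppresses
  signal steps below the noise floor and cells at realistic SNR become
  undetectable.
* **Cell detection.** Local maxima of the map above median + 8·MAD,
  accepted greedily in descending value with a minimum separation (8 px);
  the higher of two close peaks wins. Manual curation is a reproducible
  JSON edits file (`{"add": [[y,x],…], "remove": [id,…]}`) applied after
  automatic detection, or a fully user-supplied ROI set. Cells firing less
  than ~1 event/min leave too faint a footprint on a 5-min difference map
  for any automatic detector; that regime is exactly what curation is for.
* **Traces.** ROI = fixed disk of radius 6 px (chosen to cover the soma,
  ~2× the cell-profile σ; smaller disks leave the 2% amplitude threshold
  within ~4σ of trace noise, producing spurious events). F₀ = running 10th
  percentile over a 30 s window (robust to the transients themselves);
  ΔF/F₀ = (F − F₀)/F₀; detection runs on a 0.75 s (3-frame) centered moving
  average, kinetic fits on the unsmoothed trace (the moving average biases
  short rise times upward).
* **Transients.** Onset where value and slope both increase; peak where the
  rise stops; the event closes when the slope is back to flat *and* the
  trace has decayed to within 20% of the amplitude, or at the trough where
  a new above-threshold rise begins (otherwise Poisson-clumped events merge),
  or after `max_event_s` (default 10 s — the protocol names no value).
  Events below 2% peak amplitude are discarded. Kinetics come from a
  least-squares fit of A·(1 − e^−(t−t₀)/τ_r)·e^−(t−t₀)/τ_d over the event
  window; the reported amplitude is the fitted kernel peak, with fallback
  to the raw peak when a segment has <3 samples or the RMS residual
  exceeds 25% of the amplitude.
* **Classification and network metrics.** A cell is fast (neuronal) iff the
  median fitted rise time is strictly below τ* = 1.5 s; a rise of exactly
  1.5 s, or a cell with no usable fit, is slow. Slow cells are excluded
  from frequency/amplitude/synchrony; the active fraction divides active
  fast cells by *all* detected cells. Synchrony = (max over 1 s bins of the
  number of distinct active cells with an event peak in the bin) / (number
  of active cells); 1.0 when every active cell fires together, and a
  mean-co-activation alternative would be bounded the same way.
* **Measured amplitudes are diluted** relative to the cell's intrinsic
  ΔF/F₀ by non-cell background inside the ROI disk (~30% at the synthetic
  geometry); this affects any disk-ROI measurement equally and cancels in
  group comparisons.

## Expression statistics

* **Normalization.** Housekeeping genes with cross-sample mean count above
  450 are retained; each sample is scaled so the geometric mean of the
  retained set equals the grand geometric mean. The invariant (equal HK
  geomeans across samples, to 1e-9 relative) makes the operation
  idempotent.
* **DE selection.** Per-gene two-sided t-tests on log2(x+1) of the
  normalized counts, pooled-variance Student's t by default — the row-wise
  "multiple t-tests" convention of spreadsheet statistics packages, and
  exactly calibrated under a normal null at n = 3/group, where Welch's
  approximation is measurably conservative (0.035 at nominal 0.05); Welch
  remains selectable. Calls: up iff p ≤ 0.05 and FC ≥ 1.5; down iff
  p ≤ 0.05 and FC ≤ 0.66; fold change is always the ratio of linear group
  means (B/A). No multiple-testing correction is applied by default,
  matching the raw-p selection convention of nCounter panel studies; an
  optional Benjamini–Hochberg column is available. Degenerate genes (zero
  variance in both groups) get p = 1 when the means agree and p = 0
  otherwise.
* **Clustering.** Average linkage on Pearson distance 1 − r (range [0, 2]);
  zero-variance profiles are an error (correlation undefined). Merge
  heights agree with an O(n³) from-scratch implementation.
* **qPCR.** rel_expr = 2^−(Ct_gene − Ct_ref) with ATP5O as the default
  reference; isoform ratios (e.g. 4R/3R tau) are ratios of relative
  expressions, i.e. 2^−(Ct_4R − Ct_3R).
* **Control QC** (positive-control linearity R², negative-control
  mean + 2 SD background) is reported but never gates samples — there is
  no principled gating rule to apply.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed) and emit a truth
record describing the noise-free phantom exactly; SNR is defined as
(peak signal − background) / noise SD throughout.

* **Tube phantoms** (`gen_tube_phantom`): smooth random 3D curves (gentle
  bending, mostly in-plane) dilated to tubes of radius 0.8 µm (dendrite
  caliber, matching the 10 px vesselness scale at 0.133 µm/px), Gaussian
  PSF blur, Gaussian noise. Default field 512×512 px × 32 planes
  (68×68×6.4 µm — the physical 133 µm field scaled down for desk-speed
  runs) with tube surfaces kept ≥ 6 µm apart; closer tubes are not
  resolvable as separate fragments at the 10 px filter scale, because
  their vesselness halos bridge above the Otsu threshold. Placement is
  rejection sampling; an error is raised when the requested density cannot
  be placed. Not emulated: crossing/touching neurites, branching, uneven
  staining, anisotropic PSF.
* **Puncta/bar fields** (`gen_puncta_image`): disks of radius 3–7 px
  (0.4–0.9 µm puncta at the 100× pixel size — diffraction-limited sizes;
  smaller disks would be sub-resolution) or oriented bars
  ("mitochondria"), non-touching, on a uniform background. The truth
  records the exact object mask. Not emulated: intensity heterogeneity
  within objects, overlapping puncta, structured background.
* **Calcium movies** (`gen_calcium_movie`): Gaussian-profile cells,
  per-cell Poisson event trains with an optional shared network train
  (`shared_event_fraction` interpolates between independent and fully
  synchronous), rise×decay kernels scaled so the planted amplitude is the
  ΔF/F₀ *peak*, optional linear bleach, Gaussian noise. Defaults: 20 cells,
  128×128 px, 5 min at 4 Hz, amplitude 0.2, τ_r 0.5 s, τ_d 2 s, SNR 5.
  Not emulated: motion, neuropil contamination, overlapping somata,
  shot-noise statistics.
* **Count matrices** (`gen_count_matrix`): negative-binomial counts
  (gamma–Poisson, dispersion 0.1) with log-normal library-size factors so
  normalization is non-trivial; housekeeping genes are high-abundance
  (mean > 450 by construction) and never differentially expressed; planted
  DE genes get a multiplicative fold change, half up, half down. A
  `lognormal` mode draws exactly normal log-counts for null-calibration
  studies. Not emulated: probe-specific biases, batch effects,
  positive/negative control probes.
* **Ct tables** (`gen_ct_table`): Ct = Ct_ref − log2(rel_expr) + technical
  noise in cycles; exact recovery at zero noise.

Passing recovery tests on these phantoms demonstrates that the pipelines
measure what they claim under controlled conditions; it does not certify
performance on real microscopy, where the un-emulated features above
(crossing neurites, motion, background structure) are the dominant failure
modes.

## Problem sizes in the standard runs

The bundled verification runs use: tube phantoms of 1–20 fragments in the
default volume, one SNR-10 phantom of 12 fragments; one automatic-pipeline
calcium movie (20 cells, rate 2/min) plus curated-ROI movies across rates
0.5–3/min and kinetics τ_r ∈ {0.5, 3} s; a 200-replicate null for test
calibration and 10 replicates for DE recall; exhaustive clustering checks
up to 8 leaves. These sizes give stable statistics while keeping a full
verification run in minutes on one core.
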