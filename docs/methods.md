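# Methods

`cytoprofile` reimplements an image-based phenotyping pipeline for human
monocyte/macrophage populations: two-channel fluorescence scenes (DAPI for
nuclei, phalloidin for f-actin) are segmented into single cells, each cell
is summarised by a fixed vector of 228 morphometric measurements (the
"cytoprofile"), and five supervised classifiers assign each cell to one of
five phenotypes — M1 (classically activated), M2 (alternatively activated),
naive macrophage, day-0 monocyte, and day-6 monocyte. Because no microscopy
dataset accompanies the original study, a synthetic-scene generator is a
first-class component: it encodes the published qualitative morphology of
the five phenotypes and provides per-cell ground truth, so every stage of
the pipeline is testable and the published accuracy structure can be
reproduced end to end.

## Synthetic scene model

**Cell geometry.** A cell outline is a polar curve
`r(θ) = R · (1 + Σ_{k=2..6} a_k cos(kθ + φ_k))` with harmonic amplitudes
`a_k ~ U(−β/k, +β/k)`, where `β` is the archetype's boundary irregularity
(0–0.5). Low-order harmonics give lamellar and spindle-like outlines
without self-intersection. Elongation `e` (major/minor axis ratio) is
applied area-preservingly (semi-axes `R√e` and `R/√e`) and the shape is
randomly rotated. The nucleus is a disc placed at a displacement of
`nucleus_offset_frac` times the available clearance from the cell centroid,
snapped to the nearest position where it still fits strictly inside the
cell (guaranteed via the distance transform; the nucleus radius is shrunk
if no position exists).

**Channels.** The nuclear channel adds a constant per-nucleus DNA intensity
(`dna_intensity_scale`) on the background. The actin channel adds, inside
each cell, a texture field built from a Poisson spot process
(`actin_spot_density` spots per 100 px²) blurred with a per-phenotype
Gaussian sigma (`actin_smoothness`), normalised to zero mean / unit
variance within the cell and applied as a ±35% modulation of the cell's
mean actin brightness (`actin_intensity_scale`). Phenotypes therefore
differ in texture *grain* (dotted vs smooth) at matched brightness. A rim
within 2 px of the cell boundary is multiplied by `edge_rim_gain`
(cortical actin). Poisson noise is applied to the photon-scale image,
followed by additive Gaussian read noise (sd 5 by default); background is
100 arbitrary units.

**Cell-to-cell variability.** Three nuisance processes make the
populations realistic rather than idealised Gaussian blobs:

* per-cell lognormal staining gains (CV 0.12, mean 1) on both channels —
  per-pixel intensity scales are then population tendencies, not oracles;
* per-cell lognormal jitter (CV 0.2) of the actin blur sigma;
* an atypical ("outlier") subpopulation in the cultured classes (18% of
  cells): radius ×U(1.15, 1.5), elongation ×U(1.3, 1.7), irregularity
  +0.15 — the over-spread, mitotic and stacked cells that primary cultures
  contain. Day-0 monocytes are exempt: freshly isolated monocytes are the
  uniform negative-control population.

**Default archetypes** (radii in px; an image is 512×512 with 18 cells):

| phenotype | cell R | elong | irreg | nucleus R | spots/100px² | blur σ | rim | actin |
|-----------|-------|-------|-------|-----------|--------------|--------|-----|-------|
| mono_d0   | 9 ± 0.8  | 1.05 | 0.05 | 6.0 ± 0.6  | 0.5  | 2.0 | 1.0  | 42 |
| mono_d6   | 16 ± 2.5 | 1.15 | 0.14 | 10.4 ± 1.1 | 0.7  | 2.4 | 1.2  | 58 |
| naive_mac | 17 ± 2.5 | 1.35 | 0.25 | 7.8 ± 0.8  | 1.0  | 1.6 | 1.45 | 62 |
| M1        | 12 ± 1.5 | 1.8  | 0.25 | 7.0 ± 0.7  | 12.0 | 0.8 | 1.3  | 60 |
| M2        | 24 ± 3.0 | 1.2  | 0.30 | 9.0 ± 0.9  | 1.2  | 3.0 | 1.8  | 72 |

DNA intensity scale is 145 for every class: the nuclear *area* difference,
not a per-pixel brightness difference, is what separates day-6 monocytes
(largest nuclei) from naive macrophages; summed DNA intensity is then
highest for day-6 monocytes as a consequence of nucleus size. These values
were calibrated (a sanctioned free parameter of the design) so that the
five populations reproduce the published orderings — M2 largest cells,
day-6 monocytes largest nuclei, day-0 monocytes smallest and most uniform,
near-identical naive/day-6 cell-area histograms (overlap > 0.8) — and so
that the full pipeline reproduces the published accuracy structure (see
"Calibration endpoint" below). M1's spot density is high and its blur
small because a *dense* fine-grained speckle is what raises co-occurrence
entropy at a 3 px offset; sparse bright spikes produce a skewed,
low-entropy texture instead.

**What the generator does not emulate:** optics (PSF, depth of field),
illumination gradients, cell-cell clumping and debris, multi-nucleated
cells, and batch effects. Passing tests therefore demonstrate correctness
of the measurement and evaluation machinery and internal consistency of
the calibrated populations — not performance on real micrographs, whose
artefact structure is harsher than anything simulated here.

## Segmentation

Primary objects (nuclei) from the DAPI channel: global threshold → hole
filling → equivalent-diameter gate (8–60 px) → declumping by watershed on
the Gaussian-smoothed (σ 2 px) distance transform, seeded at its local
maxima with a minimum separation equal to the minimum nucleus diameter;
post-declump fragments below the minimum area are dropped and labels made
contiguous in raster order. Secondary objects (cell bodies): seeded
watershed on the inverted Gaussian-smoothed (σ 2 px) actin channel,
restricted to the actin foreground mask (threshold × `actin_threshold_offset`,
holes filled, sub-nucleus-sized specks removed) plus the seed pixels, so a
seed outside the foreground degenerates to its nucleus. Quality control
drops border-touching cells (configurable), cells without nuclei and
nuclei without cells.

The default **global threshold** for both channels is a robust background
model: median + 3 × 1.4826 × MAD. Global Otsu (also available) is bistable
on scenes dominated by a near-constant background spike with a sparse,
heterogeneous foreground: depending on the realisation it lands either
just above the background mode (everything becomes foreground) or inside
the dim-cell intensity cluster (dim monocytes are truncated), and it
degrades sharply at low cell density. The robust threshold is anchored to
the background in all these regimes; on noise-free non-touching scenes the
segmentation recovers ground-truth masks with IoU 1.0, and at default
noise ≥ 95% of cells are recovered across seeded scenes (measured 240/240).

## The 228-measurement cytoprofile

Per cell, in a fixed public order (the schema is exported and hashed):

* **shape** — 14 per object × {nucleus, cell} = 28: area, perimeter
  (polygon length through 8-connected boundary pixel centres, diagonal
  steps √2), form factor 4πA/P², compactness P²/4πA, eccentricity,
  solidity, extent, equivalent diameter, major/minor axis lengths,
  orientation (degrees in (−90, 90]), and max/mean/median distance-to-edge
  (distance-transform radius statistics);
* **intensity** — 12 per object × channel = 48: integrated, mean, median,
  population std, unscaled MAD, min, max, quartiles (linear
  interpolation), integrated and mean intensity over the boundary pixels
  ("edge"), and mass displacement (distance between binary and
  intensity-weighted centroids);
* **radial distribution** — 12 per object × channel = 48: four concentric
  bins of equal normalised distance-from-edge width (bin 4 is the core,
  measured toward the in-mask point farthest from the edge — robust for
  crescent shapes where the centroid can fall outside the mask), each with
  FracAtD (fraction of total intensity), MeanFrac (FracAtD ÷ area
  fraction) and RadialCV (CV of mean intensity over 8 angular wedges);
* **texture** — 13 Haralick statistics × object × channel × offset
  {3, 8} px = 104: in-mask intensities quantised to 8 equal-width levels
  between the in-mask min and max; symmetric gray-level co-occurrence
  matrices accumulated per direction over the 4 standard offsets with both
  pixels inside the mask; the 13 statistics averaged over directions.
  Conventions: sum-of-squares variance is centred on the marginal mean of
  the symmetric GLCM; sum variance is centred on the sum average;
  logarithms base 2. A constant in-mask region yields ASM = IDM = 1 and
  zeros elsewhere (correlation and IMC1 imputed 0 when a marginal variance
  or entropy is zero).

Degenerate values anywhere (empty radial bin, zero-variance correlation)
are imputed as 0 so profiles stay finite; an extractor *failure* (e.g. a
nucleus too small to form any co-occurrence pair) rejects the cell with
its provenance logged. Totals: 28 + 48 + 48 + 104 = 228.

## Classification protocol

Five classifiers: random forest (20 trees, unlimited depth), logistic
regression (L2, C = 1), SVM (RBF, C = 1), kNN (k = 5, Euclidean), Gaussian
naive Bayes. Features are normalised to [0, 1] by min/max statistics
fitted on the training partition only (inside every CV fold — the
no-leakage contract is asserted by test). The SVM uses the classic RBF
width γ = 1/n_features. This normalisation/kernel pairing reproduces the
conventions of the era's data-mining toolchains on which such pipelines
were built; it matters scientifically: modern variance-adaptive kernel
widths re-tune the RBF to the data scale and make the SVM competitive with
the ensemble methods, erasing the characteristic SVM underperformance on
morphometric tables that this pipeline (and the study it reproduces)
reports. With the flat classic kernel the SVM underfits gracefully — it
still identifies the starkly distinct day-0 monocytes essentially
perfectly while trailing the forest and logistic regression elsewhere.

Evaluation reports both protocols (their equivalence is not assumed):
pooled stratified 10-fold CV on the full table (per-class accuracy = class
recall = diagonal of the row-percentage confusion matrix), and a
stratified 50/50 hold-out split (floor of n·fraction per class to train)
whose fitted model supplies the held-out confusion matrix and one-vs-rest
ROC curves (thresholds swept over scores; AUC by trapezoid). Learning
curves subsample stratified training sets per fraction and evaluate on the
held-out remainder, averaged over repeats. kNN ties resolve to the first
class in sorted order; all stochastic steps (splits, folds, forests) are
driven by a single seed.

## Calibration endpoint

At desk scale (150 images, 512×512, 18 cells each → ~540 cells/class; one
CPU, ~2 minutes end to end) the default dataset yields, under pooled
10-fold CV at seed 1: random forest ≥ 96% on M1 and M2 and ≈ 89% on naive
macrophages; logistic regression the best overall; every classifier
≥ 99% on day-0 monocytes; mean per-class accuracy ranking logistic
regression > random forest > SVM > kNN; and the largest off-diagonal entry
of the day-6 monocyte confusion row is the naive-macrophage column — the
same dominant confusion the real populations show, driven here (as there)
by the near-identical cell-area distributions of the two classes.

One published relation is deliberately tested in its literal form: edge
actin intensity *correlates with cell area* across the population, and the
area-normalised edge-actin metric is higher for naive macrophages than for
day-6 monocytes. The stronger paraphrase "area-normalised edge intensity
higher for the largest cells than for the smallest" cannot hold for
rasterised cells: the metric scales as boundary/area ≈ 2/r, so the ~2.6×
radius ratio between M2 macrophages and day-0 monocytes outweighs any
plausible rim-staining ratio once the background floor is included.

## Numerical and degenerate-input choices

* Coordinates are 0-based (row, col); objects 8-connected; boundary =
  mask pixels with a 4-connected background neighbour.
* A constant image segments to zero objects (not an error); non-finite
  pixels are a validation error.
* Placement uses rejection sampling (1000 attempts per cell) with a
  3 px border margin and a dilation-based separation test; failure raises
  an error reporting the achieved count.
* Perimeter of a single-pixel or untraceable mask falls back to the
  square-equivalent 4√A so the form-factor identity stays defined.
* Dataset generation derives one child seed per image from the master
  seed (all below 2³¹); identical configuration + seed reproduces images,
  ground truth, manifests and feature tables byte-for-byte.

## Known limitations

* The 228-measurement schema is a reconstruction constrained by the
  printed total and the named families; exact equality with any
  CellProfiler export is not claimed (no Zernike moments or granularity
  spectra — the budget is filled by the four families above).
* Segmentation is classical (threshold + watershed); touching-cell
  declumping is exercised only through the analytic fused-disc case and
  adjacent-cell scenes, not dense clumps.
* Absolute accuracies on synthetic populations depend on the calibrated
  archetypes; only the qualitative structure (orderings, dominant
  confusion, class difficulty ranking) is meaningful for comparison with
  real data.
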