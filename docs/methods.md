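# Methods

This note documents the models implemented in `stainstat`, the
conventions and parameter defaults that matter for interpreting its
output, what the synthetic generators do and do not emulate, and the
design choices made where the underlying procedure left details open.

## Brightfield polarity and coordinates

All image stages assume brightfield DAB-style polarity: high intensities
are empty background or vein lumen, low intensities are stain. Inputs on
the opposite polarity (fluorescence) can be inverted with the pipeline's
`invert` flag. Coordinates are 0-based `(row, col)` with the origin at the
top-left; all tile and patch bounds are half-open. Integer images are
rescaled by their dtype maximum so all internal intensities live on a
[0, 1]-like scale; RGB input is collapsed with Rec. 709 luminance weights
(0.2126, 0.7152, 0.0722).

## Background normalization and tiling

Each image is divided by the mean of a 200×200 background patch, so the
empty-background level is mapped to 1.0 and staining depth becomes
comparable across slides regardless of illumination. The patch can be
supplied explicitly (the equivalent of a manual selection) or chosen
automatically: among 200×200 windows on a half-window stride, the
minimum-variance window whose mean lies in the top quartile of window
means — bright and flat is what background looks like. Ties go to the
first window in row-major scan order. A near-zero patch mean (< 1e-6) is
an error rather than a silent division blow-up.

The analysis ROI is a 1500×1500 square cut into an 8×8 grid. The nominal
187.5-px tile is non-integer, so cut positions are
round-half-away-from-zero of `i·1500/8`, giving
`[0, 188, 375, 563, 750, 938, 1125, 1313, 1500]` — alternating 187/188-px
tiles that exactly partition the ROI with no dropped pixels.

### Empty/vein tile filter

The ROI is Gaussian-blurred (default sigma 2.0 px — the blur radius is a
package choice, pinned by regression tests and exposed as a parameter) and
the 90th-percentile value of the blurred ROI is taken as a brightness
cutoff. A tile is discarded when strictly more than 10 % of its blurred
pixels lie strictly above that cutoff. Computing the cutoff on the blurred
ROI (not per tile, and not on the raw image) makes the drop decision
invariant to multiplying the whole ROI by a positive constant, and the
strict inequality means a perfectly constant ROI keeps all 64 tiles.

### Aggregation

Kept tiles are 3×3 block-averaged (a 187-px tile becomes 63 cells, with
ragged edge blocks averaging whatever pixels remain). Aggregation
preserves the tile mean exactly when the dimensions divide by 3 and to a
block-weighted mean otherwise.

## GLCM texture features

Each aggregated tile is quantized once — equal-width bins over the tile's
own [min, max], `n_gray` = 4, maximum clamped to level 3, constant tiles
mapping to level 0. Quantizing per tile rather than per window keeps the
meaning of a gray level stable across the tile; quantizing over the
tile's own range makes every statistic invariant to adding a constant to
the tile.

For every pixel whose window (default 3×3, odd, configurable) fits inside
the tile, pixel pairs at the four standard shifts (0° = (0,1),
45° = (−1,1), 90° = (−1,0), 135° = (−1,−1)) with both endpoints inside
the window are pooled into a single symmetric co-occurrence distribution
P, from which seven statistics are computed:

- mean `μ = Σ i·P(i,j)` and variance `Σ (i−μ)²·P(i,j)`
- contrast `Σ (i−j)²·P` and dissimilarity `Σ |i−j|·P`
- homogeneity `Σ P/(1+(i−j)²)`
- angular second moment `Σ P²`
- entropy `−Σ P·ln P` (natural log by default, log2 available; `0·ln 0 = 0`)

Pooling the four angles at the count level (rather than averaging four
statistics) matches the behavior of the multi-shift raster texture tools
this pipeline models; a per-shift co-occurrence is available for
diagnostics. Border pixels with incomplete windows are masked and excluded
from all summaries. The implementation uses integral-image box sums per
pair code, and is validated against a brute-force per-window enumeration
oracle, exhaustively on all 512 binary 3×3 images and on seeded random
tiles.

Each of the seven maps is summarized over the tile's valid pixels by mean,
sample sd (n−1), linear-interpolation (type-7) quartiles, excess kurtosis,
and moment skewness (g1) — 42 features per tile. On a constant
(zero-variance) map the sd is 0 and kurtosis/skewness are NaN-flagged
rather than 0, so degenerate tiles cannot masquerade as signal; rows with
flagged NaNs are dropped (and logged) before PCA. Quantile type and
kurtosis convention are package choices — other toolchains may differ by
convention, which the property tests tolerate.

## PCA embedding

Feature columns are centered and, by default, scaled to unit variance
before SVD. Standardization is on by default because the 42 features mix
scales (entropy in nats vs variance in squared levels); unscaled PCA would
be dominated by the variance-type features. Zero-variance columns are
dropped with a warning. The sign of each component is fixed so its
largest-magnitude loading is positive, making scores and figures
reproducible. Thumbnail scatters draw the k most extreme tiles (largest
PC1/PC2 norm) per quadrant, default k = 3.

## IHC scoring

Cells are stratified by mean stain intensity at three increasing cutoffs
(F4/80 preset 0.05/0.4/0.6, CD3 preset 0.2/0.4/0.6), with the boundary
convention that a cell exactly at a cutoff enters the higher stratum (the
convention is not dictated by the formula; it is pinned by tests). Per
region: percent-positive = 100 − %neg and
H-score = 1·%low + 2·%moderate + 3·%high. Empty regions are skipped with a
warning, never zero-filled. Vein-patch scoring restricts cells to square
patches (default 500 px) labeled central or portal; overlapping patches
are allowed (logged), in which case a cell can contribute to several
patches. Group comparison is the classical fixed-effects one-way ANOVA on
region-level scores, with explicit degenerate handling (all-identical
scores → flagged NaN instead of a 0/0). Positive-cell *detection* (the
slide-level optical-density segmentation) is upstream of this package,
which starts from per-cell tables.

## Activity score

The score is the raw signed sum of log2 expression — up-genes weighted +1,
down-genes −1 — exactly as stated for the signature it models; no per-gene
centering or z-scoring is applied by default (the raw sum is what the
score definition prescribes, though it is scale-dominated by highly
expressed genes; callers can pre-transform the matrix if they want a
standardized variant). Signature genes absent from a matrix are skipped,
never imputed, and the coverage fraction is always reported. Ortholog maps
are plain two-column tables; unmapped genes are excluded and the exclusion
fraction reported, many-to-one targets collapse to one gene, and a target
reached from both directions is removed from both sets and reported. The
sensitivity check correlates per-sample scores under the full vs a reduced
signature (Pearson), flagging zero-variance score vectors as undefined.

## Expression clustering

Each gene is centered by its across-sample median (idempotent; row medians
of the output are 0 to machine precision). Pairwise gene distance is
1 − Pearson correlation (zero-variance genes are removed first and
reported, since their correlation is undefined), clustered by average
linkage (UPGMA, via scipy's `linkage`, equivalent to R's `hclust`
average method) and cut into k clusters (default 4) by the k−1 highest
merges. Cluster labels are renumbered by decreasing size with ties broken
by the lexicographically smallest member gene, so labels are deterministic.
The implementation is checked against a naive O(n³) UPGMA oracle through
cophenetic distances. Per-cluster profiles pool centered values over the
cluster's genes and each sample group's samples and report median and
quartiles. Selecting *which* genes to cluster (e.g. by an interaction test
in a differential-expression model) is upstream; the module accepts any
gene list.

## Synthetic data

The generators define the study conditions for all tests; they are
simulators of the data's geometry, not of its chemistry.

- **Histology**: cells are anti-aliased filled disks (1-px rim falloff —
  crisp stained areas exercise the tile filter better than Gaussian
  blobs), darker than the background by a per-cell stratum factor
  (¼, ½, ¾, 1 × `stain_intensity`, stratum drawn uniformly); overlaps
  take the darker value. Defaults: 1500-px image, background 0.92, stain
  0.55, cell radius 6 px, additive Gaussian noise sd 0.02 clipped to
  [0, 1] with the clipped fraction logged. Dispersed mode scatters cells
  uniformly; clustered mode is a Thomas process (uniform parents,
  Gaussian offspring with sd `cluster_sd_px`) whose single spread knob
  controls aggregation strength. Veins are bright disks at background
  level containing no cells. Configs whose total cell area exceeds the
  image are rejected. Not emulated: RGB DAB/hematoxylin color chemistry,
  stain deconvolution, cell morphology, illumination gradients — so
  passing tests demonstrate the pipeline's behavior on controlled
  geometry, not performance on real slides.
- **Cell intensities**: four strata at configurable means with Gaussian
  jitter floored at 0; sd = 0 reproduces the means exactly, which makes
  stratum-fraction recovery an exact test.
- **Expression**: a 2×2 genotype × treatment design (3 samples per group
  by default, matching a small bulk RNA-seq cohort), per-gene constant
  baseline ~N(6, 1) on the log2 scale, noise sd 0.3. Signature up-genes
  are shifted +2 (log2) in the high-activity genotype and down-genes +2 in
  the knockout, so the signed-sum score separates genotypes by
  construction. Interaction genes follow four per-group templates chosen
  with low pairwise correlation (genotype main effect, treatment main
  effect, pure crossover, single-group spike; amplitude 1.5, spike 4.5)
  assigned round-robin, so correlation-distance clustering can recover
  them — ARI > 0.95 at the default noise. Expression is generated directly
  on the log2 scale; read-level simulation is out of scope.

## Validation study sizes

The texture→PCA separation study uses 20 images per condition
(dispersed-sparse 300 cells, dispersed-dense 1200, clustered-dense 1200
with 8 parents and sd 110 px) at the full 1500-px image size — enough
images for a stable silhouette while keeping the whole study around half a
minute. Separation is reported at two levels: per-tile silhouette of the
ground-truth groups in (PC1, PC2), and per-image silhouette after
averaging tile scores within each image. The image level is the fairer
summary for clustered tissue, where single tiles legitimately span the
whole density axis; both are computed and both exceed the 0.25 acceptance
floor at the defaults. Because denser staining pulls more pixels toward
the dark quantization levels, the GLCM mean feature decreases with cell
density, and PC1 tracks it (|r| > 0.7) — the embedding's first axis is a
cell-number axis, with texture-variability features loading on PC2.

## Known limitations

- The ROI and background patch are placed at fixed coordinates or by the
  automatic heuristic; no content-aware ROI selection.
- The GLCM window size (3×3) and blur sigma (2.0) are conventional
  defaults, not fitted quantities; results at other settings differ and
  both are exposed as parameters.
- The one-way ANOVA treats regions as independent; no nesting of regions
  within animals.
- Single-resolution rasters only: no whole-slide pyramids, registration,
  or stain deconvolution.
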