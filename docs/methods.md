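# Methods

## The quantification procedure

`thtquant` quantifies per-cell Thioflavin-T (ThT) fluorescence in
epifluorescence micrographs of bacteria. At sub-toxic concentrations ThT
stains bacterial total RNA preferentially over genomic DNA, so the mean
green-channel intensity of a cell is a proxy for its RNA content; a
downward shift of the per-cell intensity distribution between two imaging
time points indicates RNA depletion (e.g. by an induced endoribonuclease
toxin). The pipeline itself computes no biological inference — it produces
the intensity tables and the between-condition statistics.

Per image, the chain is:

1. **Green channel.** Only channel index 1 of the 8-bit RGB micrograph is
   used. Raster convention: row-major, origin top-left, `(row, col)`,
   0-based.
2. **Global Otsu threshold.** The cut level `k ∈ {0..255}` maximizing the
   between-class variance of the 256-bin histogram, reported normalized as
   `k/255`. When several cuts tie (e.g. an empty gap between two modes),
   the lowest maximizer is returned — a deterministic, documented
   tie-break. A constant image has no threshold and is skipped with a
   warning.
3. **Dataset QC.** Within one acquisition group (one condition × time
   point), the mean and sample standard deviation (n−1 denominator) of the
   per-image thresholds are computed once; an image is kept iff its
   threshold lies within `k·sd` of the mean, inclusive, with `k = 1` by
   default. Out-of-focus, empty or saturated fields move the global
   threshold and are removed by this rule. With zero spread all images are
   kept. Note the rule is distributional: with tightly clustered
   thresholds it can still trim up to roughly a third of the images.
4. **Binarization.** Foreground = intensity strictly greater than
   `t·255`, matching the normalized-threshold convention of common
   imaging toolboxes.
5. **Labeling.** 8-connected components by default (4-connectivity is a
   parameter), labels 1..n in raster-scan order of first pixel.
6. **Pre-filters.** Objects with fewer than 100 raw pixels ("less than"
   strict — a 100-px object survives) or with a pixel in the first/last
   row or column are removed.
7. **Measurement.** Interior holes are filled first and the filled mask is
   used for all three measures: area = filled pixel count; perimeter =
   pixel count of the object's unit-width boundary trace (foreground
   pixels with a background 8-neighbor); mean intensity = arithmetic mean
   of the green channel over the filled mask.
8. **Morphological filter.** Keep iff `300 ≤ area ≤ 1000` px (inclusive)
   and `perimeter ≤ 165` px — the single-cell window at the emulated
   magnification; smaller objects are debris, larger ones clumps of
   touching cells. No watershed splitting is attempted: clumps are
   discarded, not divided.
9. **Pooling and statistics.** Surviving cells are pooled across kept
   images within a group. For two groups the package reports the
   10/25/50/75/90 percentile summary per group (linear interpolation
   between order statistics), the two-sided Mann-Whitney U test, and the
   fold change.

### Perimeter definition

The perimeter of a digitized object has no unique definition. Here it is
the pixel count of the one-pixel-thick boundary of the filled object: a
10×10 square has perimeter 36 (4·10 − 4 corner-shared pixels), a single
pixel has perimeter 1. For an object with a nonempty interior this
boundary is already unit width and is counted directly; thinning such a
closed curve further would eat its corner pixels (standard thinning
removes them as topologically redundant) and silently change the hand
countable value, so it is not applied there. Only for line-like objects
with no interior — where the "boundary" degenerates to the whole object —
is the mask thinned to unit width first. Because published area/perimeter
cutoffs depend on the perimeter convention of the original analysis
environment, `perimeter_max` is a parameter, not a constant.

### Rolling-ball background subtraction

For stains that need background flattening, the background is estimated as
the grayscale opening of the image with a non-flat spherical-cap
structuring element of radius `r` px (heights `sqrt(r² − d²)`): erosion
then dilation, edge handling by replication, default radius 20 px. The
estimate is subtracted and negative residuals are clamped to 0. A flat
field maps exactly to 0; features narrower than the ball footprint are
preserved (a 3×3 plateau at radius 20 keeps >99.9% of its height). The
paraboloid ("sliding paraboloid") variant of some imaging tools is out of
scope. ThT quantification runs on the raw green channel; rolling ball is
OFF by default and exists for the DAPI/EtBr-style preprocessing path.

## Statistics

* **Mann-Whitney U**: U is computed from rank sums with midranks for
  ties and reported for the first (before) sample. The two-sided p-value
  is exact (full enumeration of the permutation null) when
  `n_a·n_b ≤ 400` and the pooled sample is tie-free, otherwise the normal
  approximation with tie and continuity corrections. If every value in
  both samples is identical the test is degenerate and p = 1 is reported.
  At 20 cells per group the approximation tracks the exact null to within
  0.005; the pipeline's pooled samples (hundreds to thousands of cells)
  are deep in the asymptotic regime.
* **Fold change**: FC = mean(after)/mean(before) of the per-cell mean
  intensities, so FC < 1 is a fluorescence decrease. The mean-ratio is the
  default because the pooled per-cell means are approximately symmetric
  and the ratio then estimates the true intensity ratio directly; a
  median-ratio mode (`fc_mode="median"`) is exposed for skewed samples.
  Neither mode claims to reproduce any specific published FC value — the
  raw micrographs behind those numbers are not deposited.
* **Percentiles**: linear interpolation (the "inclusive" order-statistic
  method); the five reported percentiles are exactly the box/whisker
  positions of the standard 10-25-50-75-90 box plot.
* p-values are stored raw in the CSV and floored in display as
  "≤ 0.001", matching common reporting style.

## Synthetic micrographs

No raw images are available for this assay, so validation uses a seeded
generator (`thtquant.synthetic`) whose defaults emulate the study
conditions:

| parameter | default | meaning |
|---|---|---|
| image size | 512×512 px | one field of view |
| cells per scene | 45 | ~10% area coverage |
| ellipse semi-axes | major 16–26 px, minor 6–10 px | filled areas ≈ 300–800 px, rod-like aspect |
| per-cell mean | N(120, 15), truncated to [0, 255] | condition-level intensity; "after" group scaled by the true ratio r |
| pixel noise | N(0, 10) | shot/read noise on the green channel |
| background | N(8, 3) | dark field with additive noise |
| debris / edge / clump fractions | 0.1 each | sub-100-px objects, edge-touching cells, merged pairs > 1000 px |

Cells are filled ellipses composited onto the background by per-pixel
maximum (red and blue channels carry background only), placed by rejection
sampling with a 2-px separation margin; clump pairs are placed to overlap
so their union exceeds the 1000-px limit. Category counts follow the
fractions deterministically after rounding. Everything is a pure function
of the seed.

**What the generator does not model**: optical point-spread blur,
photobleaching kinetics, uneven illumination, capped-rod (spherocylinder)
cell shape, cell-internal intensity structure. Ellipses have the same
behavior as rods under the area/perimeter filters, which is what the
tests exercise; passing tests therefore validate the *procedure*
(thresholding, filtering, measurement, statistics), not robustness to
real-world optics.

## Problem sizes and numerical choices

Validation experiments use 40 images per group (~1300 generated in-range
cells, ~1000–1200 pooled after QC — the scale of the real figure legends),
ratios r ∈ {0.70, 0.75, 1.00}, and 20 replicates for the null calibration
check; with these sizes the measured FC lands within ±0.01 of r and the
full suite runs in about two minutes. Degenerate inputs are handled
explicitly: constant images are skipped with a warning, a group that loses
all images to QC raises a pipeline error naming the group, zero-cell
scenes yield empty tables, and an sd of exactly 0 in QC keeps everything.
All comparisons of float thresholds use exact arithmetic on the 256-bin
histogram, so there are no tolerance knobs in segmentation.

## Known limitations

* Touching cells are removed, not split; the cell counts are therefore a
  filtered subsample, not a census, and are biased against dense fields.
* The threshold-QC rule always trims the tails of the threshold
  distribution, even for a perfectly homogeneous dataset.
* The perimeter cutoff is convention-dependent (see above); porting
  cutoffs from another analysis environment requires checking its
  perimeter definition.
* 8-bit input only; multi-page TIFFs and proprietary microscope formats
  are out of scope.
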