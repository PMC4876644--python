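# Methods

## Autocorrelogram

For image f with optional validity mask, the autocorrelogram at lag
τ = (τx, τy) is the Pearson product-moment correlation between f(x, y) and
f(x − τx, y − τy) over exactly the pixels where both positions are inside
the frame and mask-valid. No smoothing is applied at any point. Lags where
the overlap count n falls below `min_overlap` (default 20 pixels) or where
either window has zero variance are carried as missing (NaN) and excluded
from every downstream computation — they are never imputed as zero, because
a Pearson coefficient at such lags is either unreliable or undefined.

Implementation: the five per-lag sums (n, Σa, Σb, Σa², Σb², Σab) are
obtained as FFT-based correlations of the masked image, the mask, and their
squares/products. The image is mean-centred first; Pearson is exactly
invariant to this, and with centred values the numerator
n·Σab − Σa·Σb no longer cancels two large terms, so the vectorized result
agrees with a naive per-lag evaluation to ~1e−12 (tested at 1e−10).
Overlap counts are rounded to the nearest integer after the FFT. A window
counts as zero-variance when its variance term falls below
(n · global SD)² × 1e−12, a scale-free guard against FFT round-off
producing tiny negative or spurious positive variances. r is clipped to
[−1, 1] after division.

## Grid score

The score quantifies six-fold rotational symmetry of the autocorrelogram:

1. **Inner radius** — the first local minimum of the radially averaged
   valid correlation (integer-radius bins). This excludes the central peak.
2. **Peak detection** — local maxima (3×3 neighbourhood) of valid r at
   radii beyond the inner radius, thresholded at the 97.5th percentile of
   the *off-centre* valid correlations, merged within 2 px keeping the
   larger r (ties toward smaller radius). The percentile is taken over
   off-centre lags only: on aperiodic images the central peak would
   otherwise dominate the threshold and suppress all candidates,
   turning every null image into a degenerate case rather than a
   near-zero score.
3. **Annulus** — from the inner radius out to a radius chosen among 19
   candidates between 1.1× and 2.0× the median radius of the six
   innermost peaks, taking the radius that maximizes the score. The median
   radius of those six peaks is also reported as `peak_spacing_px`, the
   recovered lattice spacing.
4. **Rotation** — annulus lags are rotated by 30/60/90/120/150 degrees with
   nearest-neighbour sampling (no interpolation, consistent with the
   unsmoothed statistic); pairs where either lag is invalid or out of range
   are dropped. Each rotation contributes a Pearson correlation between
   original and rotated annulus values.
5. **Score** = min(r60, r120) − max(r30, r90, r150), which is bounded in
   [−2, 2] by construction.

Fewer than six detectable peaks, or an annulus with under 20 usable pairs
at any rotation, yields a *flagged* no-periodicity result whose score is
`None`. Group averages must skip flagged results; averaging a sentinel
number would bias them, which is why no sentinel exists.

## Cross-correlation and dorsal/ventral pairing

Colocalization of two channels is their whole-image Pearson coefficient
over jointly valid pixels, unsmoothed. For dorsoventral comparisons, one
region is taken from the dorsal half of a section and one from the ventral
half, as a pair with a shared `pair_id` and identical crop sizes (enforced);
when one half is unusable the remaining region is flagged `unpaired` rather
than dropped. Group summaries (mean ± SD per label) and two-tailed
Mann-Whitney comparisons are computed downstream from the per-region table.

## Morphometry

* **Density** is count / polygon area (cells/mm²), exact arithmetic, no
  stereological correction.
* **Dorsoventral thirds** are equal-extent along the declared dorsoventral
  axis, not equal-area: positions along the axis are anatomical levels, and
  per-third densities already normalize by each slab's geometric area
  (region ∩ slab, via polygon intersection). Proportions normalize the
  three densities to sum to 1.
* **Extent fraction** partitions a band into 100 slabs (≥ 50 required)
  along the dorsoventral axis; a slab expresses the marker when its mean
  intensity exceeds the threshold — Otsu's split of the band histogram by
  default, or an explicit threshold (the generator round-trip tests use
  0.5, the midpoint of the two-level synthetic bands). The fraction is the
  contiguous suprathreshold run from the dorsal end; suprathreshold slabs
  beyond that run ("ventral islands") are reported separately and never
  added, matching a front that advances ventrally.
* **Layer widths** are measured along the local normal to the pia at each
  sample position (dorsal/medial/ventral anchors): the normal ray is
  intersected with every boundary polyline and widths are distances between
  consecutive intersections. Boundaries out of order along the ray raise a
  geometry error. On curved (circular-arc) test geometry the measured
  widths match the radial gaps within 1%.
* **Mann-Whitney U** (two-tailed) uses midranks for ties. The p value is
  exact — the U null distribution enumerated by the standard
  count-recursion — when n_a·n_b ≤ 400 and the pooled sample has no ties;
  otherwise the normal approximation with tie correction and a 0.5
  continuity correction. The 400 threshold keeps the group sizes typical of
  per-region histology comparisons (≈ 7–16 regions) in the exact regime.
  The exact path is pinned against a brute-force permutation oracle and
  against `scipy.stats.mannwhitneyu` in the tests; scipy is never the
  implementation.

## Synthetic-histology generators

Every generator is a pure function of its config (seed included), using one
`numpy.random.default_rng` stream per call; identical configs give
bit-identical outputs. Images are floats in [0, 1]; the writers quantize to
16-bit TIFF, a positive affine map that leaves Pearson statistics
untouched.

* **Hexagonal patches** — isotropic Gaussian bumps (amplitude 0.85,
  σ = `patch_sigma_um`) on a triangular lattice with configurable spacing
  and orientation, optional isotropic Gaussian jitter of the centers and
  additive pixel noise, clipped to [0, 1]. Defaults (256×256 px at
  2 µm/px, 80 µm spacing, 12 µm patch radius) put the first
  autocorrelogram ring at 40 px, comfortably resolvable; the spacing is a
  free parameter, not calibrated to any particular micrograph. A square
  lattice variant serves as the four-fold-symmetry control.
* **Scatter** — the same bumps at homogeneous Poisson positions; the
  expected count defaults to the hexagonal lattice's blob density
  2/(√3 s²), so periodicity is the *only* difference from the lattice
  images in the discrimination tests.
* **Colocalized channel** — ch2 = ρ·z(ch1) + √(1−ρ²)·ε with z the
  standardized base image and ε independent standardized pixel noise,
  affinely mapped back to [0, 1]. The sample Pearson coefficient then
  concentrates on ρ with O(N^−1/2) fluctuation (≈ ±0.004 at 512²). ε is
  standardized after being drawn with SD `noise_sd`, so that parameter
  cannot shift the expected coefficient; it exists only as the scale of
  the raw noise draw.
* **Expression front** — intensity 1 at the dorsal end of a band falling
  to 0 across a logistic edge of scale `front_softness_um` centred at
  `front_fraction` × band length (hard step at softness 0).
* **Point patterns** — inhomogeneous Poisson by thinning: homogeneous
  candidates at the profile's maximum density, accepted with probability
  proportional to 1 + slope·(u − ½), u the normalized dorsoventral
  position. Mean density over the extent equals `density_per_mm2`;
  |slope| ≤ 2 keeps the local density nonnegative.

### What the generators do and do not emulate

They reproduce the *statistical* structure the analyses assume — lattice
geometry with jitter, shared-signal colocalization, density gradients,
expression fronts — but no cell morphology, dendrites, staining artifacts,
uneven illumination, or segmentation noise. Passing the recovery tests
therefore demonstrates that the statistics are implemented correctly and
invert the generative parameters they target; it does not validate marker
quantification on real micrographs, where thresholding and annotation
quality dominate.

## Pipeline and problem sizes

`run_study` fans one global seed out through `numpy.random.SeedSequence`
spawning (stage → age group → region/section), so stages are reproducible
in isolation and never share streams; derived seeds are reduced mod 2³¹.
The demo study uses three age groups whose generator ground truth echoes
the magnitudes reported for the developing MEC: dorsal/ventral overlap
(0.74, 0.61) → (0.14, 0.60) → (0.19, 0.20) with 8 regions per group,
layer-3 density 955 → 333 → 141 cells/mm² with 8 one-mm² sections per
group, and front fractions 0.10 → 0.40 → 1.00. Patch images are 256×256 px
(2 µm/px) with 4 µm jitter and 0.02 noise; colocalization fields 256²;
noise-pair and coefficient-recovery checks 512² over 20 seeds. These sizes
give Monte-Carlo error an order of magnitude below every stated tolerance
while keeping a full run under a minute on one core.

## Known limitations

* The annulus rule (first radial minimum inner bound; outer bound
  maximizing the score over 1.1–2.0× the ring radius) is one standard
  choice from the grid-analysis literature; other published variants
  (fixed-width annuli, ellipse-corrected autocorrelograms) can shift
  scores by a few tenths. No ellipse correction is applied.
* Autocorrelograms operate on raw intensities; binarized patch masks can
  be analysed by thresholding before the call, but no binarization is
  built in.
* Cell positions enter as annotated point tables; there is no automated
  cell detection or segmentation.
* Per-animal pooling of section densities is left to the caller:
  `density_trajectory` summarizes whatever estimates it is given
  (per-section by default).
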