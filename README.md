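# patchdev

Quantification of developing cortical patch lattices: spatial
autocorrelograms and grid scores for periodicity, Pearson cross-correlation
for marker colocalization, and point-pattern / laminar morphometry — with a
seeded synthetic-histology generator that provides ground truth for every
statistic.

## The problem

In tangential sections of rat medial entorhinal cortex (MEC), clusters
("patches") of calbindin-positive layer-2 pyramidal cells form a strikingly
regular, hexagonal-like lattice from birth onward. Developmental studies of
this system quantify:

* **periodicity** of the patch layout — is the arrangement six-fold
  symmetric, and what is its spacing?
* **colocalization** of marker channels (e.g. the immature-neuron marker
  doublecortin with calbindin) in dorsal vs ventral regions, where
  maturation proceeds along a dorsoventral gradient;
* **cell densities** of labeled neurons per region, their
  dorsal/intermediate/ventral distribution, and their change across age
  groups;
* **dorsoventral extent** of a marker front (e.g. wolframin) along a band
  such as the parasubiculum, and **layer widths** on parasagittal sections.

`patchdev` implements this whole workflow as a tested library plus CLI, for
anatomists and developmental neuroscientists who need these statistics to
be reproducible rather than buried in one-off scripts.

## The statistics

**Spatial autocorrelogram.** For an unsmoothed monochrome image f, the map
r(τx, τy) is the Pearson product-moment correlation between the image and a
copy of itself shifted by (τx, τy), computed over exactly the n overlapping
pixels:

    r(τx,τy) = [ n Σ f(x,y) f(x−τx, y−τy) − Σ f(x,y) Σ f(x−τx, y−τy) ] /
               sqrt( n Σ f(x,y)² − (Σ f(x,y))² ) /
               sqrt( n Σ f(x−τx,y−τy)² − (Σ f(x−τx,y−τy))² )

Lags with n < 20 overlapping pixels (configurable) or zero variance are
flagged invalid, never zero-filled.

**Grid score.** The annulus of the autocorrelogram containing the six
first-ring peaks is correlated with itself rotated by 30°, 60°, 90°, 120°
and 150°; the score is `min(r60, r120) − max(r30, r90, r150)`, ranging from
−2 to 2. Positive scores indicate hexagonal symmetry; a square lattice
scores negative; random scatter scores near 0.

**Spatial cross-correlation.** The colocalization of two same-size marker
channels f1, f2 is their whole-image Pearson coefficient, in [−1, 1], with
dorsal/ventral region pairing handled explicitly.

**Morphometry.** Cell densities (count / polygon area, cells/mm²),
equal-extent dorsal/intermediate/ventral partitions, marker extent
fractions along a band (contiguous suprathreshold run from the dorsal end),
layer widths measured along the pia's local normal, and two-tailed
Mann-Whitney U tests (exact enumeration for small samples).

All Pearson-based statistics are invariant to uniform linear
brightness/contrast adjustment — the only preprocessing the workflow
permits.

## Worked example

```python
from patchdev import (SynthImageConfig, gen_hex_patch_image,
                      spatial_autocorrelogram, grid_score)

# synthetic tangential section: patches 80 um apart at 2 um/pixel
cfg = SynthImageConfig(width_px=256, height_px=256, pixel_size_um=2.0,
                       lattice_spacing_um=80.0, patch_sigma_um=12.0,
                       position_jitter_um=4.0, background_noise_sd=0.02,
                       seed=3)
img = gen_hex_patch_image(cfg)
gs = grid_score(spatial_autocorrelogram(img, max_lag=100, min_overlap=20))
print(f"grid score {gs.score:.3f}, spacing {gs.peak_spacing_px:.1f} px")
```

prints

```
grid score 1.502, spacing 40.0 px
```

— a strongly positive score (six-fold symmetry detected) and the recovered
ring spacing of 40 px = 80 µm, matching the generator's ground truth. The
same image through the CLI:

```bash
patchdev synth --out hex.tif --seed 3 --jitter 4 --noise 0.02
patchdev gridscore --image hex.tif --pixel-size 2.0
```

A full synthetic study (three "age groups" with declining dorsal/ventral
colocalization, declining layer-3 density 955 → 333 → 141 cells/mm², and an
advancing marker front) runs with:

```bash
patchdev run --config run.yaml
```

writing tab-delimited tables (grid scores, per-region and summary
colocalization with Mann-Whitney comparisons, density trajectory,
dorsoventral proportions, extent fractions) plus a manifest with the config
hash and seed; the same config and seed reproduce every table byte for
byte.

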