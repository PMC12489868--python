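# Methods

## Problem and pipeline

Microvascular images of the bulbar conjunctiva, filmed through a slit lamp,
show dark curvilinear vessels on a bright, often vignetted scleral
background. Fixed-parameter CLAHE enhances such images inconsistently
because the useful tile size, clip limit and output-histogram shape depend
on each frame's exposure and content. This package tunes those parameters
per image with a multi-objective cuckoo search (MOCS) that trades contrast
gain against noise amplification.

The pipeline stages are:

1. **Luminance extraction.** RGB frames are reduced to the HSV value
   channel, V = max(R, G, B), in [0, 1].
2. **Frame selection** (sequences only). Each frame is filtered with a
   Laplacian of Gaussian and the response variance is used as a focus
   score; the highest-variance frame is kept. Defaults: σ = 2.0 px, kernel
   half-width ceil(3σ), reflect padding — the standard 3σ support captures
   essentially the whole Gaussian, and reflect padding avoids artificial
   edge response inflating the variance. Ties go to the earliest frame.
3. **Exposure classification.** Mean luminosity V_avg ≤ 0.6 is
   underexposed, (0.6, 0.8] correct, > 0.8 overexposed, with both
   boundaries in the lower class. The thresholds sit high because the
   bright sclera skews conjunctival histograms negative.
4. **Optimization and enhancement** (below), with a fixed-parameter CLAHE
   arm (8×8 tiles, clip 0.01, α 0.6) always computed as the comparator.
5. **Scoring.** Both arms are scored with the two search objectives and
   with full-reference metrics (PSNR, global SSIM) against the original.

## Rayleigh CLAHE

The image is split into `tiles_x × tiles_y` non-overlapping tiles (the
image is reflect-padded to the nearest grid multiple and cropped back).
Each tile's 256-bin histogram is clipped at
`clip_count = max(1, clip_limit · tile_pixels)` — the clip limit is a
normalized fraction of the tile pixel count, the convention under which the
searched range (0.001, 0.01] is meaningful. Excess mass is redistributed
equally over all bins; since redistribution can push bins back over the
limit, clip-and-redistribute is iterated to its fixed point (excess below
10⁻⁹ of the total, at most 100 rounds). When the limit is infeasible
(total mass > 256 · clip_count) the iteration converges to the uniform
histogram, the flattest achievable.

The transfer function maps the clipped CDF c through the Rayleigh quantile
g(c) = √(2α² ln 1/(1−c)). c is clamped at 1 − 1/tile_pixels to keep the
logarithm finite, and the per-tile mapping is affinely rescaled to span
[0, 1], so any α produces an in-range, monotone lookup table. Tile
mappings are blended bilinearly between the four nearest tile centers
(clamped to the outer ring at the borders); the interpolation is grouped
as `a + wx(b−a) + wy(c−a) + wx·wy(a−b−c+d)` so equal corner mappings pass
through exactly and a constant image stays bitwise constant.

Larger clip limits amplify both contrast and noise; α shifts the
brightness balance of the enhanced tile.

## Objectives

* **GLCM contrast** (maximize): Σ_{i,j} (i−j)² p_ij over the normalized
  gray-level co-occurrence matrix. Defaults: 8 levels by uniform binning
  of [0, 1], single offset (0, 1) (distance 1, horizontal), symmetric
  accumulation — the most widespread Haralick settings; all three are
  configurable.
* **Fast noise-variance estimate** (minimize): the image is convolved with
  N = [[1,−2,1],[−2,4,−2],[1,−2,1]], the difference of two 3×3 Laplacian
  approximations, whose response to i.i.d. noise has variance 36σ²
  while annihilating constant and linear structure. The estimator
  σ̂ = √(π/2) · Σ|I∗N| / (6(W−2)(H−2)) sums over interior pixels only.
  It is computed on the [0, 1] scale; multiply by 255 to compare with
  8-bit-scale figures.

Internally both objectives are minimized as (−contrast, noise); reported
values keep natural signs.

## Multi-objective cuckoo search

Decision vector: (tiles_x, tiles_y, clip_limit, α), searched continuously
within bounds 4–12 tiles per axis, clip 0.001–0.01, α 0.5–0.9. Tile counts
are rounded only when a vector is decoded for evaluation, keeping the walk
continuous; evaluations are cached on the decoded parameter tuple.

Default settings: population 50, 20 iterations, discovery probability
P_a = 0.75 (i.e. 25% survival), Lévy exponent β = 1.5 and step scale 0.01
of each dimension's bound range (the customary cuckoo-search choices).
Each iteration:

1. **Lévy phase.** For every nest, a cuckoo egg is proposed as
   x′ = x + step_scale · range ⊙ Lévy(β) ⊙ (x − guide), clamped to bounds,
   where the guide is a crowding-weighted random member of the current
   non-dominated archive and Lévy steps use the Mantegna sampler
   u/|v|^{1/β}. The proposal replaces a uniformly random nest if it
   dominates it; under mutual non-domination it replaces with probability
   0.5 (a diversity-preserving multi-objective analogue of "keep if
   better").
2. **Abandonment phase.** Each coordinate of each nest is replaced with
   probability P_a by x + r(x_p − x_q), r ~ U(0,1), p ≠ q random nests.
3. **Truncation.** Old and walked populations are merged and cut back to
   the population size by non-dominated sorting with crowding-distance
   tie-breaking.

An external archive of non-dominated solutions (capped at the population
size by crowding) is updated at every evaluation; the returned front and
the per-iteration history snapshots come from this archive, which makes
elitism unconditional: the front never regresses between iterations even
though the replacement rule may drop population members. Failed or
non-finite evaluations are logged and treated as dominated by everything.

The final parameter set is the **middle of the front**: members sorted by
the contrast objective, index ⌊(n−1)/2⌋, ties broken by larger crowding
distance then lower noise — a balanced trade-off rather than either
extreme. Runs are fully deterministic given the seed.

## Quality metrics

PSNR = 10 log₁₀((L−1)²/MSE) with L = 256 on the 8-bit-scaled images;
identical images report +∞ with a warning. SSIM is computed as a single
global statistic over whole-image means, variances and covariance with
C1 = (0.01·L)², C2 = (0.03·L)²; the sliding-window variant of the original
SSIM formulation is exposed as `ssim(..., mode="windowed")` but is not the
default. NIQE needs a pretrained natural-scene-statistics model and is not
reimplemented; `quality_report` accepts an external callable and records
its value verbatim.

## Synthetic phantoms

The generator emulates the features of conjunctival frames that drive the
pipeline: a bright background (default level 0.75, landing near mean
luminosity 0.70 after the radial vignette, i.e. correct exposure), dark
curvilinear vessels (seeded random walks with momentum, Gaussian
transverse profile ~3 px wide, contrast 0.25), multiplicative radial
vignette (strength 0.15), optional defocus blur, and additive Gaussian
sensor noise (σ = 0.01 on [0, 1], typical of a consumer CMOS sensor at
moderate ISO). Noise is added after blur, as sensor noise acts on the
defocused optical image, and the result is clipped to [0, 1]; the recorded
ground-truth σ refers to the pre-clipping noise, so a small bias remains
near saturation. The exposure suite adjusts the background by fixed-point
iteration until the rendered mean lands in each class interval.

What the phantoms do **not** model: specular highlights, eyelashes and
lids, physically realistic sclera texture, motion blur, demosaicing or
compression artifacts. Passing phantom tests therefore shows the
machinery is correct and the directional behavior (contrast up, noise
contained) holds on vessel-like content — not that clinical image quality
gains carry over to any particular instrument.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at phantom scale:
96×96 phantoms, 10 seeds, and a reduced search (population 15, 8
iterations) — chosen as the smallest sizes at which the directional
comparisons are stable across seeds. Estimator-recovery checks use
512×512 noise fields. Degenerate inputs are handled explicitly: constant
images enhance to constant images and score (contrast 0, noise 0);
histograms with infeasible clip limits flatten toward uniform; empty
fronts, empty sequences and out-of-range parameters raise `ValueError`.

## Known limitations

* Enhancement is grayscale-only; chroma is discarded at ingestion.
* Only the sharpest frame of a sequence is enhanced; sequence-wide
  parameter reuse is possible by applying the returned parameters to other
  frames, but no registration is provided.
* The global SSIM follows the single-window formula exactly; its values
  are systematically higher than sliding-window SSIM on textured images.
* The optimizer is single-process by design so that evaluation order
  cannot perturb seeded results.
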