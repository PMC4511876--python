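# Methods

This note documents the model behind `rcpquant`, the defaults it ships with,
and the numerical choices that are not obvious from the code.

## Pipeline model

Input is one z-stack per fluorescence channel (two colors). Processing runs
in six stages (`simulate → prep → detect → snr → integrity → coloc`), each
writing its outputs and timings to a JSON manifest so a run is fully
auditable and byte-reproducible from its seed.

1. **Projection / background correction.** `corrected = max_z − min_z`,
   clipped at 0. The minimum projection estimates per-pixel static
   background (camera offset, slide autofluorescence, illumination
   gradient); subtracting it from the maximum projection keeps any signal
   that is in focus at some z.
2. **Auto threshold.** Pixels of the corrected image are clipped to their
   [2nd, 98th] percentile range and the modal intensity is found; the
   threshold is `2 × mode`. The mode of a fluorescence image is a robust
   background-level estimate because background pixels dominate. When the
   clipped values are effectively integers the mode is taken over exact
   unique values; otherwise over a 256-bin histogram (ties resolve to the
   lower value, making the threshold conservative and deterministic).
3. **Segmentation and cluster filter.** 8-connected components above
   threshold become candidate signals. Components smaller than
   `min_area_px = 4` are discarded as shot-noise specks (a single hot pixel
   can survive a max−min projection). Components with `area > 40 px` or
   `circularity < 0.5` are excluded as clusters/debris.
4. **Local-maxima detection.** For counting sub-foci of disintegrated RCPs,
   the corrected image is Gaussian-smoothed (σ = 1 px), its median is
   subtracted (floored at 0), and strict local maxima over the 8-neighborhood
   are kept if their height exceeds a prominence floor (below).
5. **SNR.** Peak = max intensity within radius 3 of the candidate center;
   noise = sample SD (ddof = 1) of the annulus 3 < d ≤ 7;
   `SNR_dB = 20·log10(peak/sd)`. Candidates are excluded when the outer disk
   leaves the image, when another candidate lies within 2× the outer radius
   (evaluated simultaneously, not greedily, so exclusion is symmetric and
   order-independent), or when any foreign object's pixels intrude into the
   disk.
6. **Integrity statistic.** Each signal is paired with its Euclidean nearest
   neighbor (directed: n signals → n pairs). The same-color frequency is
   compared against a Monte Carlo null of uniform random placement with the
   per-color counts fixed. Nearest-neighbor ties resolve to the smallest
   (row, col) lexicographically, so the statistic is permutation-invariant.
7. **Colocalization.** Slide: pixel intersection-over-union of the two
   binarized channels (an empty union returns 0 with a flag rather than
   NaN). Solution phase: per-channel components at ≥ 35 PMT counts, size
   2–30 px inclusive; components from the two channels that share pixels are
   merged into one entity via union-find; an entity positive in both
   channels is dual-colored. Dual fractions across conditions are compared
   with one-way ANOVA and Fisher's LSD (pairwise t-tests on the pooled MSE,
   df = N − k, unadjusted).

## Parameters and defaults

| Parameter | Default | Rationale |
|---|---|---|
| `DiskGeometry(inner, outer)` | 3, 7 px | inner disk covers a diffraction-limited spot at ~1.3 px PSF σ; annulus is local background |
| `max_area_px` | 40 | single RCP upper bound at this magnification |
| `min_circularity` | 0.5 | separates round spots from elongated debris/clusters |
| `min_area_px` | 4 | smallest component a real PSF can produce; kills hot pixels |
| `smoothing_sigma_px` | 1.0 | matches PSF scale; suppresses pixel noise before maxima search |
| `min_prominence` | `None` → 5 × 1.4826 × MAD | robust 5σ noise floor; see below |
| `mc_replicates` | 10 | SD of the null is already ≲ 0.4 percentage points at realistic counts |
| MC null field | 1040 × 1388 px | camera sensor size of the slide experiments |
| PMT threshold / size gate | 35 counts, 2–30 px | solution-phase instrument settings |
| Scene: image, z | 512 × 512, 16 levels | study imaging conditions |
| Scene: spots per color | 100 | dense enough for statistics, sparse enough to avoid heavy merging |
| Scene: PSF σ (xy, z) | 1.3, 1.0 | diffraction-limited spot at the study pixel size |
| Scene: amplitude | 200 (lognormal, CV 0.2) | bright spot over background 40 + gradient 20 |
| Scene: noise | Poisson + Gaussian SD 5 | shot noise plus read noise |
| Scene: sub-foci per dispersed RCP | 1 + Poisson(1.5), truncated to [1, 6] | a few fragments, occasionally many |
| Scene: fragment displacement | isotropic, SD 4 px, truncated at 3σ | fragments stay near the parent |

## What the generator emulates — and what it does not

The generator renders RCPs as 3-D Gaussian blobs on a background with a
linear gradient, applies Poisson and Gaussian noise, and quantizes to
uint16. Compact and dispersed scenes built from the same seed share parent
positions and per-RCP total amplitude exactly (the parent-level random draws
happen before any mode-specific draws), so detection-rate and SNR contrasts
between modes reflect geometry alone. A dispersed RCP splits its amplitude
across sub-foci by a symmetric Dirichlet draw, conserving total signal.

Not emulated: optical aberrations and a realistic Airy/defocus PSF, spectral
bleed-through between channels, photobleaching, uneven focus across the
field, autofluorescent debris, and spot-size dependence on amplification
time. Conclusions about absolute detection rates on real data should not be
drawn from the generator; it exists to validate the statistics against
known ground truth.

## Numerical choices

- **Perimeter estimate.** Circularity uses
  `perimeter = (π/4) × (4-neighbor exposed edge count)`. The raw edge count
  is a taxicab perimeter that overestimates Euclidean length (for a large
  rasterized disk of radius r it approaches 8r instead of 2πr); the π/4
  factor makes the estimate exact in that limit. Without it a rasterized
  disk of radius 3 scores circularity ≈ 0.46 and a typical genuine spot
  would fail the 0.5 gate.
- **Prediction-interval t-test.** The observed frequency is a single number,
  not a sample, so a one-sample t-test of the null replicates against it
  ignores the observation's own sampling variability and is anti-
  conservative. The statistic used,
  `t = (f_obs − mean_null) / (sd_null · √(1 + 1/n_rep))` with
  df = `n_rep − 1`, is the standard test of whether a new observation is
  consistent with a sample.
- **Robust prominence floor.** The maxima detector's default floor is
  `5 × 1.4826 × MAD` of the *smoothed* image, computed before median
  subtraction (after flooring at zero, the MAD of a mostly-zero image
  collapses to 0 and the floor vanishes). 1.4826 × MAD estimates the noise
  SD robustly against the bright-spot tail; 5σ keeps the false-positive rate
  per image negligible.
- **Determinism.** All randomness flows from `numpy.random.default_rng`
  seeds; derived seeds are drawn from a master generator in a fixed order
  and kept below 2³¹. Ties (threshold mode, nearest neighbors, plateau
  maxima) have documented deterministic resolutions. Plateau maxima report
  the plateau centroid.
- **Degenerate inputs.** Zero-SD annuli raise; constant images short-circuit
  the mode estimate; group comparisons with all-identical values report a
  degenerate result with p = 1 instead of NaN; zero-variance duplicate
  groups are excluded from ANOVA with a warning.

## Problem sizes and runtime

The Monte Carlo null at the largest experiment size (71,356 points × 10
replicates) runs in ~2 s using a k-d tree with a slow path only for exact
ties. A full pipeline run on a default 512×512×16 two-channel scene takes a
few seconds; the complete test suite runs in about two minutes.

## Limitations

- The 2-D statistics assume projections; overlapping spots at different z
  merge into one component.
- The integrity null assumes spatial uniformity; real slides with density
  gradients would need an inhomogeneous null (e.g. a permutation null over
  observed positions, provided as `permutation_null`).
- Fisher's LSD does not control the family-wise error rate beyond the
  ANOVA gate.
- The mode threshold assumes background-dominated images; dense fields
  (>~20% foreground) bias the mode upward.
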